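"""Ready-made simulation designs used by the worked analyses and tests.

Both designs mirror the emulated study layout: 30 case and 18 control
samples, methylation on the beta scale, expression on an intensity scale.

``default_study_config``
    Twelve planted motifs, two per regulation pattern. Magnitudes are chosen
    so each motif can clear both screens: the pair's all-case correlation
    must exceed 0.25 in magnitude (which rules out perfectly symmetric
    reversals — their case-wide correlation averages to ~0) and the
    stratum contrast must exceed |delta| = 0.7. "Intensify" motifs sit near
    the geometric boundary |r_low| < |r_high| - 0.7, which forces a weak
    baseline (|r_low| just above the 0.25 direction-calling threshold) —
    the same geometry that makes intensify patterns rare in real data.

``recovery_config``
    The benchmark design for sensitivity/FDR scoring: 50 symmetric reverse
    motifs (r_low = +0.8, r_high = -0.8) plus 450 recorded null
    site-pair combinations, evaluated on the ground-truth combo universe
    (the interaction screen is not part of this benchmark).
"""
from __future__ import annotations

from .simulate import (PlantedMotif, SimulationConfig, gene_name, site_name,
                       tf_name)

__all__ = ["default_study_config", "recovery_config", "global_null_config",
           "recovery_combos", "DEFAULT_PATTERN_RS"]

# two (r_low, r_high) pairs per pattern; see module docstring for the geometry
DEFAULT_PATTERN_RS: dict[str, list[tuple[float, float]]] = {
    "relax_inhibition": [(-0.90, -0.15), (-0.85, -0.10)],
    "intensify_inhibition": [(-0.28, -0.99), (-0.26, -0.98)],
    "relax_activation": [(0.90, 0.15), (0.85, 0.10)],
    "intensify_activation": [(0.28, 0.99), (0.26, 0.98)],
    "reverse_activation": [(-0.95, 0.30), (-0.90, 0.35), (-0.95, 0.40)],
    "reverse_inhibition": [(0.95, -0.30), (0.90, -0.35), (0.95, -0.40)],
}


def default_study_config(seed: int = 0) -> SimulationConfig:
    motifs = []
    core_sites = []  # strong motifs share one split -> a dense core module
    i = 0
    for pattern in sorted(DEFAULT_PATTERN_RS):
        for r_low, r_high in DEFAULT_PATTERN_RS[pattern]:
            i += 1
            motifs.append(PlantedMotif(site=site_name(i), tf=tf_name(i),
                                       gene=gene_name(i), r_low=r_low,
                                       r_high=r_high, differential=True))
            if pattern in ("reverse_activation", "reverse_inhibition"):
                core_sites.append(site_name(i))
    return SimulationConfig(
        n_case=30, n_control=18, n_tf=60, n_gene=100, n_meth=150,
        planted_motifs=tuple(motifs), n_null_pairs=50, n_null_sites=50,
        site_groups=(tuple(core_sites),),
        noise_sd=1.0, seed=seed,
    )


def recovery_config(seed: int = 0, n_planted: int = 50, n_null: int = 450,
                    r_low: float = 0.8, r_high: float = -0.8) -> SimulationConfig:
    # benchmark profiles are emitted on the log2 (latent) scale — the scale
    # the pipeline's preprocessing restores and the planted r values refer to
    motifs = [
        PlantedMotif(site=site_name(i + 1), tf=tf_name(i + 1),
                     gene=gene_name(i + 1), r_low=r_low, r_high=r_high)
        for i in range(n_planted)
    ]
    return SimulationConfig(
        n_case=30, n_control=18,
        n_tf=n_planted + 40, n_gene=n_planted + 40,
        n_meth=max(n_planted + n_null, 1),
        planted_motifs=tuple(motifs), n_null_pairs=n_null, n_null_sites=n_null,
        noise_sd=1.0, seed=seed, expression_scale="log2",
    )


def global_null_config(seed: int = 0, n_motifs: int = 200) -> SimulationConfig:
    """No planted structure at all: the calibration bench for the
    permutation test (every site-pair combination is null)."""
    return SimulationConfig(
        n_case=30, n_control=18, n_tf=n_motifs + 10, n_gene=n_motifs + 10,
        n_meth=n_motifs, n_null_pairs=n_motifs, n_null_sites=n_motifs,
        seed=seed, expression_scale="log2",
    )


def recovery_combos(truth) -> list[tuple[str, str, str]]:
    """Planted motif keys plus one null site per null pair."""
    combos = [k for k in truth.motifs]
    combos += [(s, tf, g) for s, (tf, g) in zip(truth.null_sites,
                                                truth.null_pairs)]
    return combos
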