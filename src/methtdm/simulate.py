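"""Synthetic cohort generator with planted methylation-TF-gene motifs.

Emulates the study design the pipeline targets: ~30 case and ~18 control
placenta-style samples with three sample-matched profiles (TF expression,
gene expression, methylation beta values), a TF->gene interaction catalog,
gene-set (GMT) libraries and a drug->gene catalog — all with a recorded
ground truth so every downstream stage can be scored.

Generative model (fully deterministic given the seed)
-----------------------------------------------------
* Methylation lives on the beta [0,1] scale. A planted motif's site is
  bimodal in case samples (equal-weight Beta mixture concentrated near 0.2
  and near 0.8) so the analysis's top/bottom 40% strata genuinely differ in
  methylation; a *differential* site additionally shifts its case mean away
  from control (control draws concentrate near the upper mode). Null sites
  are unimodal noise around a per-site baseline, identical in both groups.
* Expression is generated as ``2**latent`` where the latent values are
  Gaussian, so the pipeline's log2 step recovers exactly the planted
  correlation structure. For a planted motif, case samples whose site value
  falls in the lower (upper) half of that site's case values draw their
  (TF, gene) latent pair from a bivariate normal with correlation ``r_low``
  (``r_high``). The analysis's 40% tails are strict subsets of these
  median-split halves, so the planted contrast survives the stricter split.
  All other rows are independent noise.
* Planted motifs must use pairwise-disjoint TF, gene and site rows: one
  feature row cannot carry two different planted joint distributions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, OmicsMatrix
from .errors import ConfigError
from .patterns import classify_pattern
from . import io as mio

__all__ = [
    "PlantedMotif",
    "SimulationConfig",
    "GroundTruth",
    "simulate_profiles",
    "simulate_interaction_catalog",
    "simulate_annotation_files",
    "tf_name",
    "gene_name",
    "site_name",
]


def tf_name(i: int) -> str:
    return f"TF{i:04d}"


def gene_name(i: int) -> str:
    return f"G{i:04d}"


def site_name(i: int) -> str:
    return f"cg{i:07d}"


@dataclass(frozen=True)
class PlantedMotif:
    """Ground-truth motif: ``site`` modulates the ``tf``-``gene`` correlation
    from ``r_low`` (low-methylation half) to ``r_high`` (high half)."""

    site: str
    tf: str
    gene: str
    r_low: float
    r_high: float
    differential: bool = True

    def __post_init__(self):
        for name, r in (("r_low", self.r_low), ("r_high", self.r_high)):
            if not abs(r) < 1:
                raise ConfigError(f"{name}={r} infeasible: need |r| < 1")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.site, self.tf, self.gene)

    @property
    def true_pattern(self) -> str:
        # geometric label from the true correlations (no tau gate here)
        return classify_pattern(self.r_low, self.r_high, tau=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    n_case: int = 30
    n_control: int = 18
    n_tf: int = 40
    n_gene: int = 60
    n_meth: int = 80
    planted_motifs: tuple[PlantedMotif, ...] = ()
    n_null_pairs: int = 0
    n_null_sites: int = 0
    noise_sd: float = 1.0
    seed: int = 0
    # groups of planted sites that share one underlying bimodal split, so
    # every pair planted on a group member is modulated by every member —
    # the generative analogue of a dense core module
    site_groups: tuple[tuple[str, ...], ...] = ()
    # measurement-scale knobs
    expression_scale: str = "intensity"  # "intensity" (2**latent) or "log2"
    expression_mean_range: tuple[float, float] = (5.0, 10.0)
    meth_noise_sd: float = 0.05
    meth_mix_low: tuple[float, float] = (4.0, 16.0)   # Beta params, mode ~0.2
    meth_mix_high: tuple[float, float] = (16.0, 4.0)  # Beta params, mode ~0.8
    # differential sites: control samples concentrate near full methylation,
    # putting the case-control mean shift around 0.4
    meth_ctrl_beta: tuple[float, float] = (36.0, 4.0)

    def __post_init__(self):
        if self.n_case < 5 or self.n_control < 5:
            raise ConfigError("need n_case >= 5 and n_control >= 5")
        for name in ("n_tf", "n_gene", "n_meth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.expression_scale not in ("intensity", "log2"):
            raise ConfigError("expression_scale must be 'intensity' or 'log2'")
        tfs = {m.tf for m in self.planted_motifs}
        genes = {m.gene for m in self.planted_motifs}
        sites = {m.site for m in self.planted_motifs}
        keys = [m.key for m in self.planted_motifs]
        if len(set(keys)) != len(keys):
            raise ConfigError("planted motif (site, tf, gene) keys must be unique")
        if (len(tfs) != len(keys) or len(genes) != len(keys)
                or len(sites) != len(keys)):
            raise ConfigError(
                "planted motifs must use pairwise-disjoint TF/gene/site rows"
            )
        universe_tf = {tf_name(i + 1) for i in range(self.n_tf)}
        universe_gene = {gene_name(i + 1) for i in range(self.n_gene)}
        universe_site = {site_name(i + 1) for i in range(self.n_meth)}
        for m in self.planted_motifs:
            if m.tf not in universe_tf or m.gene not in universe_gene \
                    or m.site not in universe_site:
                raise ConfigError(f"planted motif {m.key} references out-of-range ids")
        grouped = [s for grp in self.site_groups for s in grp]
        if len(set(grouped)) != len(grouped):
            raise ConfigError("site_groups must be disjoint")
        if not set(grouped) <= sites:
            raise ConfigError("site_groups may only contain planted motif sites")
        if self.n_null_sites > self.n_meth - len(sites):
            raise ConfigError("n_null_sites exceeds available non-planted sites")
        n_free_pairs = (self.n_tf - len(tfs)) * (self.n_gene - len(genes))
        if self.n_null_pairs > n_free_pairs:
            raise ConfigError("n_null_pairs exceeds available non-planted pairs")

    @property
    def tf_ids(self) -> list[str]:
        return [tf_name(i + 1) for i in range(self.n_tf)]

    @property
    def gene_ids(self) -> list[str]:
        return [gene_name(i + 1) for i in range(self.n_gene)]

    @property
    def site_ids(self) -> list[str]:
        return [site_name(i + 1) for i in range(self.n_meth)]


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream scoring."""

    motifs: dict[tuple[str, str, str], dict] = field(default_factory=dict)
    differential_sites: list[str] = field(default_factory=list)
    correlated_pairs: list[tuple[str, str]] = field(default_factory=list)
    null_pairs: list[tuple[str, str]] = field(default_factory=list)
    null_sites: list[str] = field(default_factory=list)
    tf_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    site_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "motifs": {
                "|".join(k): v for k, v in self.motifs.items()
            },
            "differential_sites": self.differential_sites,
            "correlated_pairs": ["|".join(p) for p in self.correlated_pairs],
            "null_pairs": ["|".join(p) for p in self.null_pairs],
            "null_sites": self.null_sites,
            "tf_ids": self.tf_ids,
            "gene_ids": self.gene_ids,
            "site_ids": self.site_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            motifs={tuple(k.split("|")): v for k, v in d["motifs"].items()},
            differential_sites=list(d["differential_sites"]),
            correlated_pairs=[tuple(p.split("|")) for p in d["correlated_pairs"]],
            null_pairs=[tuple(p.split("|")) for p in d["null_pairs"]],
            null_sites=list(d["null_sites"]),
            tf_ids=list(d["tf_ids"]),
            gene_ids=list(d["gene_ids"]),
            site_ids=list(d["site_ids"]),
        )


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    case = [f"PE{i + 1:02d}" for i in range(config.n_case)]
    control = [f"CT{i + 1:02d}" for i in range(config.n_control)]
    return case, control


def simulate_profiles(config: SimulationConfig
                      ) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, GroundTruth]:
    """Generate (tf, gene, methylation) matrices plus the ground truth."""
    rng = np.random.default_rng(config.seed)
    case_ids, control_ids = _sample_ids(config)
    samples = case_ids + control_ids
    labels = pd.Series([CASE] * len(case_ids) + [CONTROL] * len(control_ids),
                       index=samples, name="group")
    n_case, n_all = len(case_ids), len(samples)

    planted_by_site = {m.site: m for m in config.planted_motifs}

    # ---- methylation -----------------------------------------------------
    meth = np.empty((config.n_meth, n_all))
    a_lo, b_lo = config.meth_mix_low
    a_hi, b_hi = config.meth_mix_high
    # sites in one group share the mixture-component assignment, hence
    # (nearly) the same low/high split of the case samples
    group_comp: dict[str, np.ndarray] = {}
    for grp in config.site_groups:
        comp = rng.random(n_case) < 0.5
        for s in grp:
            group_comp[s] = comp
    for i, site in enumerate(config.site_ids):
        motif = planted_by_site.get(site)
        if motif is None:
            mu = rng.uniform(0.2, 0.8)
            meth[i] = np.clip(rng.normal(mu, config.meth_noise_sd, n_all), 0, 1)
        else:
            comp = group_comp.get(site)
            if comp is None:
                comp = rng.random(n_case) < 0.5
            case_vals = np.where(comp, rng.beta(a_lo, b_lo, n_case),
                                 rng.beta(a_hi, b_hi, n_case))
            if motif.differential:
                ctrl_vals = rng.beta(*config.meth_ctrl_beta, len(control_ids))
            else:
                comp_c = rng.random(len(control_ids)) < 0.5
                ctrl_vals = np.where(comp_c, rng.beta(a_lo, b_lo, len(control_ids)),
                                     rng.beta(a_hi, b_hi, len(control_ids)))
            meth[i] = np.concatenate([case_vals, ctrl_vals])

    meth_df = pd.DataFrame(meth, index=config.site_ids, columns=samples)

    # ---- expression latents ---------------------------------------------
    lo, hi = config.expression_mean_range
    tf_mu = rng.uniform(lo, hi, config.n_tf)
    gene_mu = rng.uniform(lo, hi, config.n_gene)
    tf_lat = tf_mu[:, None] + config.noise_sd * rng.standard_normal((config.n_tf, n_all))
    gene_lat = gene_mu[:, None] + config.noise_sd * rng.standard_normal(
        (config.n_gene, n_all))

    tf_index = {t: i for i, t in enumerate(config.tf_ids)}
    gene_index = {g: i for i, g in enumerate(config.gene_ids)}
    site_index = {s: i for i, s in enumerate(config.site_ids)}

    truth = GroundTruth(tf_ids=config.tf_ids, gene_ids=config.gene_ids,
                        site_ids=config.site_ids)
    for motif in config.planted_motifs:
        ti, gi, si = tf_index[motif.tf], gene_index[motif.gene], site_index[motif.site]
        case_meth = meth[si, :n_case]
        # median split of the case samples for this site; analysis's 40% tails
        # are strict subsets of these halves
        order = np.argsort(case_meth, kind="stable")
        half = n_case - n_case // 2
        low_mask = np.zeros(n_case, bool)
        low_mask[order[:half]] = True
        z1 = rng.standard_normal(n_case)
        z2 = rng.standard_normal(n_case)
        gene_z = np.empty(n_case)
        for mask, r in ((low_mask, motif.r_low), (~low_mask, motif.r_high)):
            gene_z[mask] = r * z1[mask] + np.sqrt(1 - r * r) * z2[mask]
        tf_lat[ti, :n_case] = tf_mu[ti] + config.noise_sd * z1
        gene_lat[gi, :n_case] = gene_mu[gi] + config.noise_sd * gene_z
        truth.motifs[motif.key] = {
            "r_low": motif.r_low,
            "r_high": motif.r_high,
            "pattern": motif.true_pattern,
            "differential": motif.differential,
        }
        truth.correlated_pairs.append((motif.tf, motif.gene))
        if motif.differential:
            truth.differential_sites.append(motif.site)

    if config.expression_scale == "intensity":
        tf_vals, gene_vals = 2.0 ** tf_lat, 2.0 ** gene_lat
    else:
        tf_vals, gene_vals = tf_lat, gene_lat
    tf_df = pd.DataFrame(tf_vals, index=config.tf_ids, columns=samples)
    gene_df = pd.DataFrame(gene_vals, index=config.gene_ids, columns=samples)

    # ---- recorded nulls --------------------------------------------------
    planted_tfs = {m.tf for m in config.planted_motifs}
    planted_genes = {m.gene for m in config.planted_motifs}
    planted_sites = set(planted_by_site)
    free_tfs = [t for t in config.tf_ids if t not in planted_tfs]
    free_genes = [g for g in config.gene_ids if g not in planted_genes]
    if config.n_null_pairs:
        flat = rng.choice(len(free_tfs) * len(free_genes), size=config.n_null_pairs,
                          replace=False)
        truth.null_pairs = [
            (free_tfs[k // len(free_genes)], free_genes[k % len(free_genes)])
            for k in sorted(flat)
        ]
    truth.null_sites = [s for s in config.site_ids
                        if s not in planted_sites][: config.n_null_sites]

    return (
        OmicsMatrix(tf_df, labels),
        OmicsMatrix(gene_df, labels),
        OmicsMatrix(meth_df, labels),
        truth,
    )


def simulate_interaction_catalog(truth: GroundTruth, n_extra: int,
                                 seed: int) -> pd.DataFrame:
    """Planted TF->gene pairs plus ``n_extra`` distinct random decoys."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = list(truth.correlated_pairs)
    seen = set(pairs)
    guard = 0
    while len(pairs) < len(truth.correlated_pairs) + n_extra:
        p = (truth.tf_ids[rng.integers(len(truth.tf_ids))],
             truth.gene_ids[rng.integers(len(truth.gene_ids))])
        if p in seen:
            guard += 1
            if guard > 1000 * (n_extra + 1):
                raise ConfigError("cannot draw enough distinct decoy pairs")
            continue
        seen.add(p)
        pairs.append(p)
    return pd.DataFrame(pairs, columns=["tf", "gene"])


def simulate_annotation_files(genes: list[str], seed: int,
                              background: list[str] | None = None,
                              outdir: str | Path | None = None,
                              n_sets: int = 15,
                              set_size_range: tuple[int, int] = (8, 25),
                              enriched_size: int = 10,
                              n_drugs: int = 40,
                              hub_targets: int = 13,
                              hub_name: str = "DRUG_HUB",
                              ) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Gene-set library with one set enriched by construction, plus a
    drug->gene catalog with one designated high-degree drug.

    ``genes`` is the query-like list the enriched set and the hub drug are
    built from; ``background`` (default: ``genes``) is the pool the random
    sets and the decoy drugs draw from. If ``outdir`` is given, writes
    ``gene_sets.gmt`` and ``drug_catalog.tsv`` there.
    """
    if not genes:
        raise ConfigError("need a nonempty gene list")
    rng = np.random.default_rng(seed)
    pool = list(background) if background is not None else list(genes)

    sets: dict[str, list[str]] = {}
    sets["SET_ENRICHED"] = list(genes[: min(enriched_size, len(genes))])
    lo, hi = set_size_range
    for i in range(n_sets - 1):
        size = int(rng.integers(min(lo, len(pool)), min(hi, len(pool)) + 1))
        members = sorted(rng.choice(pool, size=size, replace=False).tolist())
        sets[f"SET_{i + 1:03d}"] = members

    rows: list[tuple[str, str]] = []
    if n_drugs >= 1:
        for g in genes[: min(hub_targets, len(genes))]:
            rows.append((hub_name, g))
    for i in range(n_drugs - 1):
        k = int(rng.integers(1, 4))
        for g in rng.choice(pool, size=min(k, len(pool)), replace=False):
            rows.append((f"DRUG{i + 1:03d}", g))
    drug_df = pd.DataFrame(rows, columns=["drug", "gene"]).drop_duplicates()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_gmt(sets, outdir / "gene_sets.gmt")
        mio.write_pairs(drug_df, outdir / "drug_catalog.tsv")
    return sets, drug_df


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Same design, different seed (convenience for multi-seed studies)."""
    return replace(config, seed=seed)
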