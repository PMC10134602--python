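"""Synthetic longitudinal multi-omics cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
two donor groups sampled at up to five ordered timepoints (before
pregnancy, trimesters 1-3, post-partum) with intra-donor correlation,
per-donor and per-sample covariates, beta-scale methylation generated on
the M-value scale, overdispersed negative-binomial counts with >= 4-fold
library-size variation, and a configurable fraction of features carrying
a planted *rebound*: an effect at the 3rd trimester that reverses
post-partum, identically directed in both groups. A companion PPI graph
and gene-set collection with a planted dense neighborhood / enriched
disease set allow end-to-end recovery tests of the module and enrichment
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (
    TIMEPOINT_ORDER,
    CpGAnnotation,
    OmicsMatrix,
    SampleTable,
    ValidationError,
)

#: Relative within-pregnancy time profile of a planted rebound effect:
#: zero at the T1 baseline (and BP), ramping through T2 to the full
#: effect at T3, then back to baseline post-partum.
REBOUND_PROFILE = {"BP": 0.0, "T1": 0.0, "T2": 0.5, "T3": 1.0, "PP": 0.0}


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults follow the study design the generator emulates: 11 disease
    and 7 control donors, five ordered timepoints with the before-
    pregnancy visit absent in controls, moderate intra-donor correlation
    and mildly overdispersed counts.
    """

    n_donors_per_group: dict[str, int] = field(
        default_factory=lambda: {"MS": 11, "HC": 7}
    )
    timepoints: tuple[str, ...] = TIMEPOINT_ORDER
    n_cpgs: int = 2000
    n_genes: int = 1000
    frac_rebound: float = 0.02
    effect_m: float = 2.0
    effect_lfc: float = 2.0
    rho_donor: float = 0.5
    dispersion: float = 0.1
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "memory_fraction": 0.5, "viability": 0.2}
    )
    missing_pattern: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"HC": ("BP",)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_rebound <= 1.0:
            raise ValidationError(f"frac_rebound must be in [0, 1], got {self.frac_rebound}")
        if not 0.0 <= self.rho_donor < 1.0:
            raise ValidationError(f"rho_donor must be in [0, 1), got {self.rho_donor}")
        if self.dispersion < 0:
            raise ValidationError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.n_cpgs < 10 or self.n_genes < 10:
            raise ValidationError("n_cpgs and n_genes must each be >= 10")
        for g, n in self.n_donors_per_group.items():
            if n < 1:
                raise ValidationError(f"n_donors_per_group[{g!r}] must be positive")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValidationError("timepoints must be unique")
        order = [t for t in TIMEPOINT_ORDER if t in self.timepoints]
        if tuple(order) != tuple(self.timepoints):
            raise ValidationError(
                f"timepoints must respect the order {TIMEPOINT_ORDER}, got {self.timepoints}"
            )
        bad = set(self.timepoints) - set(TIMEPOINT_ORDER)
        if bad:
            raise ValidationError(f"unknown timepoints {sorted(bad)}")


@dataclass
class TruthSet:
    """Planted ground truth of a generated cohort."""

    rebound_cpgs: set[str]
    rebound_genes: set[str]
    planted_module_genes: set[str]
    cpg_effects: dict[str, float]
    gene_effects: dict[str, float]

    def write_json(self, path: str | Path) -> None:
        payload = {
            "rebound_cpgs": sorted(self.rebound_cpgs),
            "rebound_genes": sorted(self.rebound_genes),
            "planted_module_genes": sorted(self.planted_module_genes),
            "cpg_effects": self.cpg_effects,
            "gene_effects": self.gene_effects,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            rebound_cpgs=set(d["rebound_cpgs"]),
            rebound_genes=set(d["rebound_genes"]),
            planted_module_genes=set(d["planted_module_genes"]),
            cpg_effects=d["cpg_effects"],
            gene_effects=d["gene_effects"],
        )


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def cpg_ids(n: int) -> list[str]:
    return [f"cg{i:07d}" for i in range(n)]


def _sample_table(config: CohortConfig, rng: np.random.Generator) -> SampleTable:
    rows = []
    for group in sorted(config.n_donors_per_group):
        omitted = set(config.missing_pattern.get(group, ()))
        for i in range(config.n_donors_per_group[group]):
            donor = f"{group}{i + 1:02d}"
            age = float(np.round(rng.normal(30.0, 3.0), 1))
            for t in config.timepoints:
                if t in omitted:
                    continue
                rows.append(
                    {
                        "sample": f"{donor}_{t}",
                        "donor": donor,
                        "group": group,
                        "timepoint": t,
                        "cell_type": "CD4",
                        "state": "resting",
                        "age": age,
                        "memory_fraction": float(
                            np.clip(rng.normal(0.45, 0.08), 0.05, 0.95)
                        ),
                        "viability": float(np.clip(rng.normal(0.90, 0.04), 0.5, 1.0)),
                    }
                )
    df = pd.DataFrame(rows).set_index("sample")
    return SampleTable(df)


def generate_cohort(
    config: CohortConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleTable, CpGAnnotation, TruthSet]:
    """Generate paired methylation and expression data with planted rebound.

    Methylation is built on the M-value scale as a per-CpG baseline plus
    planted time effects, centered covariate terms, a donor random
    intercept (variance set so the intra-donor correlation equals
    ``rho_donor``) and Gaussian noise, then mapped to beta values.
    Counts are negative-binomial with the same design structure on the
    log2 scale and library sizes varying log-uniformly over a 4-fold
    range. Rebound features get +effect at T3 relative to the T1
    baseline and the reverse post-partum (sign randomised per feature,
    identical in both groups). Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_samples, rng_meth, rng_expr, rng_annot = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    samples = _sample_table(config, rng_samples)
    df = samples.data
    n_samp = len(df)
    donors = df["donor"].to_numpy()
    donor_levels = pd.unique(donors)
    donor_idx = pd.Series(range(len(donor_levels)), index=donor_levels)[donors].to_numpy()
    time_profile = np.array([REBOUND_PROFILE[t] for t in df["timepoint"]])

    cov = {
        "age": df["age"].to_numpy() - df["age"].mean(),
        "memory_fraction": df["memory_fraction"].to_numpy() - df["memory_fraction"].mean(),
        "viability": df["viability"].to_numpy() - df["viability"].mean(),
    }
    cov_term = sum(
        config.covariate_effects.get(name, 0.0) * values
        for name, values in cov.items()
    )

    cpgs = cpg_ids(config.n_cpgs)
    genes = gene_ids(config.n_genes)
    n_reb_cpg = int(round(config.frac_rebound * config.n_cpgs))
    n_reb_gene = int(round(config.frac_rebound * config.n_genes))
    rebound_cpgs = cpgs[:n_reb_cpg]
    rebound_genes = genes[:n_reb_gene]

    # --- methylation ---------------------------------------------------
    # baseline M-values: bimodal (mostly methylated / unmethylated) with
    # an intermediate component; planted CpGs sit in the dynamic range
    # so that an M-scale shift is visible on the beta scale
    comp = rng_meth.choice(3, size=config.n_cpgs, p=[0.4, 0.4, 0.2])
    mu_m = np.where(
        comp == 0,
        rng_meth.normal(-3.0, 1.0, config.n_cpgs),
        np.where(
            comp == 1,
            rng_meth.normal(3.0, 1.0, config.n_cpgs),
            rng_meth.normal(0.0, 1.0, config.n_cpgs),
        ),
    )
    if n_reb_cpg:
        mu_m[:n_reb_cpg] = rng_meth.uniform(-1.5, 1.5, n_reb_cpg)
    sigma_m = np.exp(rng_meth.normal(np.log(0.3), 0.25, config.n_cpgs))

    sign_cpg = rng_meth.choice([-1.0, 1.0], size=n_reb_cpg)
    effect_cpg = np.zeros(config.n_cpgs)
    effect_cpg[:n_reb_cpg] = sign_cpg * config.effect_m

    m_vals = _signal_matrix(
        mu=mu_m,
        effect=effect_cpg,
        time_profile=time_profile,
        cov_term=cov_term,
        sigma=sigma_m,
        rho=config.rho_donor,
        donor_idx=donor_idx,
        n_donors=len(donor_levels),
        rng=rng_meth,
    )
    beta = expit(m_vals * np.log(2.0))
    beta_mat = OmicsMatrix(pd.DataFrame(beta, index=cpgs, columns=df.index), "beta")

    # --- expression ----------------------------------------------------
    base_logcpm = rng_expr.normal(5.0, 1.5, config.n_genes)
    if n_reb_gene:
        base_logcpm[:n_reb_gene] = rng_expr.normal(5.0, 1.0, n_reb_gene)
    sigma_e = np.exp(rng_expr.normal(np.log(0.25), 0.25, config.n_genes))
    sign_gene = rng_expr.choice([-1.0, 1.0], size=n_reb_gene)
    effect_gene = np.zeros(config.n_genes)
    effect_gene[:n_reb_gene] = sign_gene * config.effect_lfc

    logcpm = _signal_matrix(
        mu=base_logcpm,
        effect=effect_gene,
        time_profile=time_profile,
        cov_term=0.5 * cov_term,
        sigma=sigma_e,
        rho=config.rho_donor,
        donor_idx=donor_idx,
        n_donors=len(donor_levels),
        rng=rng_expr,
    )
    lib = np.exp(rng_expr.uniform(np.log(1.5e6), np.log(6e6), n_samp))
    mu_counts = 2.0**logcpm * lib[None, :] / 1e6
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng_expr.gamma(shape, mu_counts / shape)
    else:
        lam = mu_counts
    counts = rng_expr.poisson(lam).astype(np.int64)
    counts_mat = OmicsMatrix(pd.DataFrame(counts, index=genes, columns=df.index), "count")

    annotation = _annotation(cpgs, genes, n_reb_cpg, n_reb_gene, rng_annot)

    truth = TruthSet(
        rebound_cpgs=set(rebound_cpgs),
        rebound_genes=set(rebound_genes),
        planted_module_genes=set(rebound_genes),
        cpg_effects={c: float(e) for c, e in zip(rebound_cpgs, effect_cpg[:n_reb_cpg])},
        gene_effects={g: float(e) for g, e in zip(rebound_genes, effect_gene[:n_reb_gene])},
    )
    return beta_mat, counts_mat, samples, annotation, truth


def _signal_matrix(
    mu: np.ndarray,
    effect: np.ndarray,
    time_profile: np.ndarray,
    cov_term: np.ndarray | float,
    sigma: np.ndarray,
    rho: float,
    donor_idx: np.ndarray,
    n_donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """features x samples latent signal with donor random intercepts.

    The donor intercept standard deviation is sigma * sqrt(rho/(1-rho)),
    which makes the correlation between any two same-donor samples equal
    to rho while cross-donor samples are uncorrelated.
    """
    n_feat, n_samp = mu.size, donor_idx.size
    sd_donor = sigma * np.sqrt(rho / (1.0 - rho))
    donor_int = rng.normal(0.0, 1.0, (n_feat, n_donors)) * sd_donor[:, None]
    noise = rng.normal(0.0, 1.0, (n_feat, n_samp)) * sigma[:, None]
    cov_row = np.broadcast_to(np.asarray(cov_term, dtype=float), (n_samp,))
    return (
        mu[:, None]
        + np.outer(effect, time_profile)
        + cov_row[None, :]
        + donor_int[:, donor_idx]
        + noise
    )


def _annotation(
    cpgs: list[str],
    genes: list[str],
    n_reb_cpg: int,
    n_reb_gene: int,
    rng: np.random.Generator,
) -> CpGAnnotation:
    """CpG -> gene map: rebound CpGs fan into rebound genes round-robin;
    other CpGs mostly map to one random background gene, ~10% to two,
    and ~10% carry no annotation."""
    rows = []
    for i in range(n_reb_cpg):
        gene = genes[i % n_reb_gene] if n_reb_gene else rng.choice(genes)
        rows.append({"cpg": cpgs[i], "gene": gene})
    background = genes[n_reb_gene:] if n_reb_gene < len(genes) else genes
    for cpg in cpgs[n_reb_cpg:]:
        u = rng.random()
        if u < 0.10:
            continue  # unannotated probe
        rows.append({"cpg": cpg, "gene": str(rng.choice(background))})
        if u > 0.90:
            rows.append({"cpg": cpg, "gene": str(rng.choice(background))})
    return CpGAnnotation(pd.DataFrame(rows).drop_duplicates())


def generate_ppi(
    n_genes: int,
    planted,
    attach_m: int = 3,
    extra_density: float = 0.3,
    seed: int = 0,
    genes: list[str] | None = None,
) -> nx.Graph:
    """Scale-free PPI graph with a planted dense neighborhood.

    A preferential-attachment graph (``attach_m`` edges per new node) is
    relabelled to gene identifiers, then edges are added among the
    ``planted`` genes until their internal edge density reaches
    ``extra_density``. Every edge carries an integer combined score in
    [700, 1000]; the graph is simple (no self-loops or parallel edges).
    """
    if attach_m < 1:
        raise ValidationError(f"attach_m must be >= 1, got {attach_m}")
    rng = np.random.default_rng(seed)
    ids = genes if genes is not None else gene_ids(n_genes)
    if len(ids) != n_genes:
        raise ValidationError("gene id list length differs from n_genes")
    planted = set(planted)
    unknown = planted - set(ids)
    if unknown:
        raise ValidationError(f"planted genes outside the universe: {sorted(unknown)[:5]}")
    if extra_density > 0 and len(planted) < 2:
        raise ValidationError("extra_density needs at least 2 planted genes")

    base = nx.barabasi_albert_graph(n_genes, attach_m, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(base, dict(enumerate(ids)))

    if len(planted) >= 2 and extra_density > 0:
        planted_sorted = sorted(planted)
        n_p = len(planted_sorted)
        target = int(np.ceil(extra_density * n_p * (n_p - 1) / 2))
        possible = [
            (a, b)
            for i, a in enumerate(planted_sorted)
            for b in planted_sorted[i + 1 :]
            if not graph.has_edge(a, b)
        ]
        current = sum(
            1
            for i, a in enumerate(planted_sorted)
            for b in planted_sorted[i + 1 :]
            if graph.has_edge(a, b)
        )
        need = max(0, target - current)
        if need > 0:
            chosen = rng.choice(len(possible), size=min(need, len(possible)), replace=False)
            for j in chosen:
                graph.add_edge(*possible[j])

    for a, b in graph.edges:
        graph[a][b]["score"] = int(rng.integers(700, 1001))
    return graph


def generate_gene_sets(
    universe,
    planted,
    n_sets: int = 20,
    overlap_frac: float = 0.5,
    set_size: int = 50,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Gene-set collection with one designated enriched "disease" set.

    The disease set contains ``overlap_frac`` of the planted genes
    (rounded) plus random fillers up to ``set_size``; the remaining
    ``n_sets - 1`` sets are uniform draws from the universe.
    """
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValidationError(f"overlap_frac must be in [0, 1], got {overlap_frac}")
    universe = sorted(set(universe))
    planted = sorted(set(planted))
    unknown = set(planted) - set(universe)
    if unknown:
        raise ValidationError(f"planted genes outside universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)

    n_overlap = int(round(overlap_frac * len(planted)))
    core = list(rng.choice(planted, size=n_overlap, replace=False)) if n_overlap else []
    non_planted = [g for g in universe if g not in set(planted)]
    n_fill = max(0, set_size - len(core))
    fill = list(rng.choice(non_planted, size=min(n_fill, len(non_planted)), replace=False))
    sets = {"disease": set(core) | set(fill)}
    for i in range(1, n_sets):
        size = min(set_size, len(universe))
        sets[f"random_set_{i:02d}"] = set(rng.choice(universe, size=size, replace=False))
    return sets


def write_cohort(
    outdir: str | Path,
    beta: OmicsMatrix,
    counts: OmicsMatrix,
    samples: SampleTable,
    annotation: CpGAnnotation,
    truth: TruthSet,
) -> dict[str, str]:
    """Write all cohort artifacts as TSV/JSON; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    beta.write_tsv(paths["beta"])
    counts.write_tsv(paths["counts"])
    samples.write_tsv(paths["samples"])
    annotation.write_tsv(paths["annotation"])
    truth.write_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
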