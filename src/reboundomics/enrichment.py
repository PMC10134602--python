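"""Gene-set enrichment, GWAS SNP-to-gene mapping and correlation conservation.

All enrichment here is overlap-based: Fisher's exact test on the 2x2
membership table for single target lists, and one-sided hypergeometric
tails with Benjamini-Hochberg correction across a GMT collection for
pathway analysis. The background (universe) follows the convention of
the differential pipeline: all measured genes, optionally extended by
the PPI-network genes when module genes are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CpGAnnotation, OmicsMatrix, SampleTable, ValidationError
from .differential import bh_adjust  # noqa: F401  (re-exported: same adjustment everywhere)

#: Sentinel reported when the sample odds ratio is infinite (bc = 0).
OR_INF_SENTINEL = float("inf")


@dataclass
class EnrichmentResult:
    """Overlap statistics of a query gene set against one target set."""

    name: str
    overlap: int
    query_size: int
    target_size: int
    universe_size: int
    odds_ratio: float
    p: float
    adj_p: float | None = None

    @property
    def gene_ratio(self) -> float:
        return self.overlap / self.query_size if self.query_size else 0.0


def fisher_enrichment(
    query, target, universe, alternative: str = "greater", name: str = "target"
) -> EnrichmentResult:
    """Fisher's exact test of query/target overlap within a universe.

    The 2x2 table counts universe genes by query and target membership;
    the reported odds ratio is the sample odds ratio ad/bc (infinite when
    bc = 0, reported as the ``inf`` sentinel).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query) & universe
    target = set(target) & universe
    a = len(query & target)
    b = len(query - target)
    c = len(target - query)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative=alternative)
    if a * d == 0 and b * c == 0:
        odds = 0.0 if a == 0 else OR_INF_SENTINEL
    elif b * c == 0:
        odds = OR_INF_SENTINEL
    else:
        odds = a * d / (b * c)
    return EnrichmentResult(
        name=name,
        overlap=a,
        query_size=len(query),
        target_size=len(target),
        universe_size=len(universe),
        odds_ratio=float(odds),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def pathway_enrichment(
    query,
    genesets: dict[str, set[str]],
    measured,
    network_genes=None,
    universe_mode: str = "measured",
    p_adj_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query against a GMT collection.

    The universe is the measured genes, extended by the network genes
    under ``universe_mode='measured_plus_network'`` (the background rule
    used when module genes -- which may include unmeasured network
    genes -- are tested). Gene sets are intersected with the universe;
    p-values are one-sided tails, BH-adjusted across sets.
    """
    if universe_mode not in ("measured", "measured_plus_network"):
        raise ValidationError(f"unknown universe_mode {universe_mode!r}")
    universe = set(measured)
    if universe_mode == "measured_plus_network":
        if network_genes is None:
            raise ValidationError("measured_plus_network requires network_genes")
        universe |= set(network_genes)
    query = set(query) & universe
    if not query:
        raise ValidationError("query is empty after intersection with the universe")

    n_u, n_q = len(universe), len(query)
    rows = []
    for name, members in genesets.items():
        members = set(members) & universe
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, n_u, len(members), n_q)) if members else 1.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": n_q,
                "universe_size": n_u,
                "gene_ratio": k / n_q,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] <= p_adj_max
    return out.sort_values("p")


# ---------------------------------------------------------------------------
# GWAS SNP -> nearest-TSS gene mapping
# ---------------------------------------------------------------------------

def gwas_snps_to_genes(
    snps: pd.DataFrame,
    tss: pd.DataFrame,
    p_max: float = 1e-6,
    window: tuple[int, int] = (-3000, 3000),
) -> tuple[set[str], int]:
    """Map significant SNPs to the gene with the nearest TSS.

    ``snps`` needs columns id, chrom, pos, p (positions 1-based);
    ``tss`` needs gene, chrom, tss_pos, strand. Each SNP with p < p_max
    is assigned to the gene whose TSS is closest, provided the signed,
    strand-aware distance (upstream negative) falls inside ``window``.
    Ties go to the lexicographically smaller gene id. Returns the gene
    set and the count of SNPs skipped for lying on chromosomes absent
    from the TSS table.
    """
    for col in ("id", "chrom", "pos", "p"):
        if col not in snps.columns:
            raise ValidationError(f"SNP table missing column {col!r}")
    for col in ("gene", "chrom", "tss_pos", "strand"):
        if col not in tss.columns:
            raise ValidationError(f"TSS table missing column {col!r}")

    sig = snps[snps["p"] < p_max]
    genes: set[str] = set()
    n_skipped = 0
    by_chrom = {c: t.sort_values(["tss_pos", "gene"]) for c, t in tss.groupby("chrom")}
    lo, hi = window
    for _, snp in sig.iterrows():
        t = by_chrom.get(snp["chrom"])
        if t is None:
            n_skipped += 1
            continue
        dist_abs = (t["tss_pos"] - snp["pos"]).abs()
        best = dist_abs.min()
        hits = t.loc[dist_abs == best]
        gene_row = hits.sort_values("gene").iloc[0]
        # signed distance from TSS to SNP in the gene's reading direction
        signed = snp["pos"] - gene_row["tss_pos"]
        if gene_row["strand"] == "-":
            signed = -signed
        if lo <= signed <= hi:
            genes.add(gene_row["gene"])
    return genes, n_skipped


def tss_from_bed(bed: pd.DataFrame) -> pd.DataFrame:
    """Convert a BED-like table (0-based half-open) to a 1-based TSS table.

    Expects columns chrom, start, end, gene, strand; the TSS is ``start``
    for + strand genes and ``end`` for - strand genes, converted to
    1-based coordinates.
    """
    for col in ("chrom", "start", "end", "gene", "strand"):
        if col not in bed.columns:
            raise ValidationError(f"BED table missing column {col!r}")
    tss_pos = np.where(bed["strand"] == "-", bed["end"], bed["start"] + 1)
    return pd.DataFrame(
        {
            "gene": bed["gene"],
            "chrom": bed["chrom"],
            "tss_pos": tss_pos,
            "strand": bed["strand"],
        }
    )


# ---------------------------------------------------------------------------
# CpG-gene correlation conservation
# ---------------------------------------------------------------------------

def correlation_conservation(
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    annotation: CpGAnnotation,
    samples: SampleTable,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Test whether CpG-gene regulatory strength is conserved across groups.

    For each annotated CpG-gene pair measured in both omics, the Spearman
    correlation between methylation and expression is computed per group
    over that group's paired samples. Absolute correlations are binned
    into within-group deciles, and for every decile a Fisher exact test
    asks whether pairs falling in that decile in one group also fall in
    it in the other. Conserved regulation yields odds ratios above 1
    across deciles.
    """
    common_samples = meth.sample_ids.intersection(expr.sample_ids)
    df = samples.data.loc[samples.data.index.intersection(common_samples)]
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, found {groups}")

    pairs = annotation.table[
        annotation.table["cpg"].isin(meth.feature_ids)
        & annotation.table["gene"].isin(expr.feature_ids)
    ].drop_duplicates(subset=["cpg", "gene"])
    if pairs.empty:
        raise ValidationError("no annotated CpG-gene pair measured in both omics")

    abs_rho = {}
    for group in groups:
        ids = df.index[df["group"] == group]
        if len(ids) < 4:
            raise ValidationError(f"group {group!r} has fewer than 4 paired samples")
        m = meth.values.loc[pairs["cpg"], ids].to_numpy()
        e = expr.values.loc[pairs["gene"], ids].to_numpy()
        # row-wise Spearman: rank within samples then Pearson
        mr = stats.rankdata(m, axis=1)
        er = stats.rankdata(e, axis=1)
        mr = mr - mr.mean(axis=1, keepdims=True)
        er = er - er.mean(axis=1, keepdims=True)
        denom = np.sqrt((mr**2).sum(axis=1) * (er**2).sum(axis=1))
        rho = np.where(denom > 0, (mr * er).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
        abs_rho[group] = np.abs(rho)

    n_pairs = len(pairs)
    bins = {}
    for group in groups:
        # decile membership within the group (0 .. n_bins-1)
        ranks = stats.rankdata(abs_rho[group], method="ordinal") - 1
        bins[group] = np.minimum((ranks * n_bins) // n_pairs, n_bins - 1)

    rows = []
    g1, g2 = groups
    for d in range(n_bins):
        in1 = bins[g1] == d
        in2 = bins[g2] == d
        a = int((in1 & in2).sum())
        b = int((in1 & ~in2).sum())
        c = int((~in1 & in2).sum())
        dd = int((~in1 & ~in2).sum())
        _, p = stats.fisher_exact([[a, b], [c, dd]], alternative="greater")
        if b * c == 0:
            odds = 0.0 if a * dd == 0 else OR_INF_SENTINEL
        else:
            odds = a * dd / (b * c)
        rows.append(
            {"decile": d + 1, "overlap": a, "n_group1": a + b, "n_group2": a + c,
             "odds_ratio": float(odds), "p": float(p)}
        )
    return pd.DataFrame(rows).set_index("decile")
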