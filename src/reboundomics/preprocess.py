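"""Probe/gene filtering, beta<->M transforms, CPM filtering and TMM factors.

Methylation enters as beta values (fractions in [0, 1]) and is tested on
the M-value scale, M = log2(beta / (1 - beta)). Expression enters as raw
counts and is normalised by trimmed-mean-of-M-values (TMM) scaling factors
before log-CPM computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormFactors, OmicsMatrix, ValidationError


@dataclass
class ProbeQC:
    """Per-probe array quality metrics used by :func:`filter_probes`.

    detection_p and bead_count are probes x samples DataFrames;
    has_gc_start / near_snp are boolean Series indexed by probe.
    """

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    has_gc_start: pd.Series
    near_snp: pd.Series

    def __post_init__(self) -> None:
        p = self.detection_p.to_numpy()
        if np.nanmin(p) < 0 or np.nanmax(p) > 1:
            raise ValidationError("detection p-values must lie in [0, 1]")
        if np.nanmin(self.bead_count.to_numpy()) < 0:
            raise ValidationError("bead counts must be >= 0")

    @classmethod
    def all_passing(cls, probes, samples) -> "ProbeQC":
        """QC object under which every probe survives filtering."""
        probes, samples = pd.Index(probes), pd.Index(samples)
        return cls(
            detection_p=pd.DataFrame(0.0, index=probes, columns=samples),
            bead_count=pd.DataFrame(100, index=probes, columns=samples),
            has_gc_start=pd.Series(True, index=probes),
            near_snp=pd.Series(False, index=probes),
        )


def filter_probes(
    beta: OmicsMatrix,
    qc: ProbeQC,
    det_p_max: float = 0.01,
    min_beads: int = 3,
) -> OmicsMatrix:
    """Remove probes failing array quality control.

    A probe is retained only if, in every sample, its detection p-value is
    below ``det_p_max`` and its bead count is at least ``min_beads``, and
    it has a GC start and is not near a SNP. Samples are never touched.
    """
    missing = beta.feature_ids.difference(qc.detection_p.index)
    if len(missing):
        raise ValidationError(
            f"QC table missing {len(missing)} probes, e.g. {list(missing[:5])}"
        )
    det = qc.detection_p.loc[beta.feature_ids, beta.sample_ids]
    beads = qc.bead_count.loc[beta.feature_ids, beta.sample_ids]
    keep = (
        (det.to_numpy() < det_p_max).all(axis=1)
        & (beads.to_numpy() >= min_beads).all(axis=1)
        & qc.has_gc_start.loc[beta.feature_ids].to_numpy()
        & ~qc.near_snp.loc[beta.feature_ids].to_numpy()
    )
    return OmicsMatrix(beta.values.loc[keep], beta.kind)


def beta_m_transform(x: OmicsMatrix, to: str, eps: float = 1e-6) -> OmicsMatrix:
    """Convert beta values to M-values or back.

    M = log2(beta / (1 - beta)) with beta clipped to [eps, 1 - eps];
    the inverse is beta = 2^M / (1 + 2^M). The transform is strictly
    monotone and round-trips to ~1e-9 away from the clipping boundary.
    """
    if to not in ("m", "beta"):
        raise ValidationError(f"target scale must be 'm' or 'beta', got {to!r}")
    if to == "m":
        if x.kind != "beta":
            raise ValidationError(f"expected beta input, got kind={x.kind!r}")
        b = np.clip(x.to_numpy(), eps, 1.0 - eps)
        vals = np.log2(b / (1.0 - b))
    else:
        if x.kind != "m":
            raise ValidationError(f"expected M-value input, got kind={x.kind!r}")
        m = x.to_numpy()
        # expit on the natural-log scale for numerical stability
        from scipy.special import expit

        vals = expit(m * np.log(2.0))
    return OmicsMatrix(
        pd.DataFrame(vals, index=x.feature_ids, columns=x.sample_ids), to
    )


def filter_low_count_genes(
    counts: OmicsMatrix, cpm_min: float = 10.0, frac: float = 0.7
) -> OmicsMatrix:
    """Drop genes with low counts-per-million in most samples.

    A gene is removed when its raw CPM (library size = pre-filter column
    sum) falls below ``cpm_min`` in at least ``frac`` of the samples;
    equivalently it is kept when CPM >= cpm_min in more than ``1 - frac``
    of samples.
    """
    if counts.kind != "count":
        raise ValidationError(f"expected count matrix, got kind={counts.kind!r}")
    x = counts.to_numpy()
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        bad = list(counts.sample_ids[lib == 0])
        raise ValidationError(f"samples with zero library size: {bad}")
    cpm = x / lib * 1e6
    n = x.shape[1]
    low_frac = (cpm < cpm_min).sum(axis=1) / n
    keep = low_frac < frac
    return OmicsMatrix(counts.values.loc[keep], "count")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    a_cutoff: float,
) -> float:
    """Scaling factor of one library against the reference.

    Per-gene log ratios M are doubly trimmed (by M and by average
    abundance A), then averaged with inverse asymptotic binomial-variance
    weights; the factor is 2**(weighted mean).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    fin = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks as in R's rank(): average ties
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: OmicsMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for count libraries.

    The reference sample is the one whose 75th-percentile CPM is closest
    to the mean 75th percentile (unless ``ref_sample`` names one). Factors
    are rescaled so that their geometric mean is 1; a pure sequencing-depth
    difference therefore yields factors of 1, being carried entirely by
    the library sizes.
    """
    if counts.kind != "count":
        raise ValidationError(f"expected count matrix, got kind={counts.kind!r}")
    x = counts.to_numpy()
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValidationError("library sizes must be positive")
    n_samples = x.shape[1]
    if n_samples < 2:
        warnings.warn("fewer than 2 samples: TMM factors set to 1", stacklevel=2)
        return NormFactors(counts.sample_ids, lib, np.ones(n_samples))

    if ref_sample is None:
        q75 = np.array(
            [np.quantile(x[:, j] / lib[j], 0.75) for j in range(n_samples)]
        )
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = counts.sample_ids.get_loc(ref_sample)

    factors = np.array([
        _tmm_pair(
            x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
            logratio_trim, sum_trim, a_cutoff,
        )
        for j in range(n_samples)
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(counts.sample_ids, lib, factors)


def log_cpm(
    counts: OmicsMatrix, factors: NormFactors, prior: float = 0.5
) -> OmicsMatrix:
    """log2 counts-per-million with prior counts and effective library sizes.

    logCPM = log2((count + prior) / (lib * factor + 2 * prior) * 1e6).
    """
    if counts.kind != "count":
        raise ValidationError(f"expected count matrix, got kind={counts.kind!r}")
    nf = factors.reindex(counts.sample_ids)
    x = counts.to_numpy()
    eff = nf.lib_size * nf.factors
    vals = np.log2((x + prior) / (eff + 2.0 * prior) * 1e6)
    return OmicsMatrix(
        pd.DataFrame(vals, index=counts.feature_ids, columns=counts.sample_ids),
        "logcpm",
    )
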