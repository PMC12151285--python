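"""Matrix filtering, cross-omic sample intersection and normalisation.

The filtering rules mirror common multi-omics practice for TCGA-style data:
drop any feature (then any sample) whose fraction of zero-or-missing entries
exceeds ``max_bad_fraction`` (default 0.20, strict inequality — a feature
sitting exactly at the boundary survives), then keep only samples present in
all omics.  Counts are normalised with median-of-ratios size factors;
methylation beta values are median-imputed and clamped away from zero so the
downstream transform, which takes log2(beta), stays bounded.

Order is fixed and documented because results depend on it: features first,
then samples, then the cross-omic intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gainet.io_formats import OmicsKind, OmicsMatrix, PromoterMap


class PreprocessError(ValueError):
    pass


@dataclass
class FilterReport:
    """Bookkeeping of what filtering removed, per omic and per axis."""

    features_removed: dict[str, list[str]] = field(default_factory=dict)
    samples_removed: dict[str, list[str]] = field(default_factory=dict)
    samples_retained: list[str] = field(default_factory=list)
    n_features_before: dict[str, int] = field(default_factory=dict)
    n_features_after: dict[str, int] = field(default_factory=dict)
    n_samples_before: dict[str, int] = field(default_factory=dict)
    n_samples_after: dict[str, int] = field(default_factory=dict)
    size_factors: dict[str, dict[str, float]] = field(default_factory=dict)


def _bad_fraction(values: np.ndarray, axis: int) -> np.ndarray:
    """Fraction of entries per row (axis=1) or column (axis=0) that are zero or missing."""
    bad = np.isnan(values) | (values == 0)
    return bad.mean(axis=axis)


def filter_features(m: OmicsMatrix, max_bad_fraction: float = 0.20) -> tuple[OmicsMatrix, list[str]]:
    """Drop features whose zero-or-missing fraction strictly exceeds the cap.

    Returns the filtered matrix (surviving order preserved) and the removed
    feature ids.  Raises :class:`PreprocessError` if nothing survives.
    """
    if not (0 <= max_bad_fraction < 1):
        raise ValueError("max_bad_fraction must be in [0, 1)")
    frac = _bad_fraction(m.values, axis=1)
    keep = frac <= max_bad_fraction
    removed = [f for f, k in zip(m.feature_ids, keep) if not k]
    if not keep.any():
        raise PreprocessError(f"all features removed from {m.kind.value} matrix")
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(kept_ids, m.sample_ids, m.values[keep], m.kind), removed


def filter_samples(m: OmicsMatrix, max_bad_fraction: float = 0.20) -> tuple[OmicsMatrix, list[str]]:
    """Column-wise analogue of :func:`filter_features`."""
    if not (0 <= max_bad_fraction < 1):
        raise ValueError("max_bad_fraction must be in [0, 1)")
    frac = _bad_fraction(m.values, axis=0)
    keep = frac <= max_bad_fraction
    removed = [s for s, k in zip(m.sample_ids, keep) if not k]
    if not keep.any():
        raise PreprocessError(f"all samples removed from {m.kind.value} matrix")
    kept_ids = [s for s, k in zip(m.sample_ids, keep) if k]
    return OmicsMatrix(m.feature_ids, kept_ids, m.values[:, keep], m.kind), removed


def intersect_samples(ms: list[OmicsMatrix]) -> list[OmicsMatrix]:
    """Restrict every matrix to the common samples, ordered by the first matrix."""
    if not ms:
        raise ValueError("no matrices given")
    common = set(ms[0].sample_ids)
    for m in ms[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise PreprocessError("no samples shared by all omics matrices")
    ordered = [s for s in ms[0].sample_ids if s in common]
    return [m.subset(sample_ids=ordered) for m in ms]


def compute_size_factors(m: OmicsMatrix) -> np.ndarray:
    """Median-of-ratios size factors for a counts matrix.

    The reference is the per-feature geometric mean over samples, restricted
    to features with strictly positive counts everywhere; each sample's size
    factor is the median over those features of count/reference.
    """
    if m.kind not in (OmicsKind.MRNA_COUNTS, OmicsKind.MIRNA_COUNTS):
        raise ValueError("size factors are defined for count matrices only")
    vals = m.values
    if np.isnan(vals).any():
        raise PreprocessError("size-factor normalisation requires a complete matrix")
    all_positive = np.all(vals > 0, axis=1)
    if not all_positive.any():
        raise PreprocessError(
            "no feature has all-positive counts; add a pseudocount before normalising"
        )
    log_ref = np.log(vals[all_positive]).mean(axis=1)  # per-feature log geometric mean
    log_ratios = np.log(vals[all_positive]) - log_ref[:, None]
    return np.exp(np.median(log_ratios, axis=0))


def size_factor_normalize(m: OmicsMatrix) -> tuple[OmicsMatrix, np.ndarray]:
    """Divide each sample's counts by its median-of-ratios size factor."""
    sf = compute_size_factors(m)
    return OmicsMatrix(m.feature_ids, m.sample_ids, m.values / sf, m.kind), sf


def impute_and_clamp_beta(m: OmicsMatrix, beta_floor: float = 1e-3) -> OmicsMatrix:
    """Median-impute missing beta values per feature, then clamp to [beta_floor, 1].

    The clamp keeps log2(beta), used by the methylation modulating factor,
    finite; a beta of exactly 0 would make that factor diverge.
    """
    if m.kind is not OmicsKind.METHYLATION_BETA:
        raise ValueError("beta imputation applies to methylation matrices only")
    vals = m.values.copy()
    for i in range(vals.shape[0]):
        row = vals[i]
        mask = np.isnan(row)
        if mask.all():
            raise PreprocessError(
                f"feature {m.feature_ids[i]!r} is entirely missing; filter it first"
            )
        if mask.any():
            row[mask] = np.median(row[~mask])
    np.clip(vals, beta_floor, 1.0, out=vals)
    return OmicsMatrix(m.feature_ids, m.sample_ids, vals, m.kind)


def restrict_promoter_map(p: PromoterMap, max_distance_bp: int = 1500) -> PromoterMap:
    """Keep CpG→gene rows with 0 <= distance <= max_distance_bp (inclusive)."""
    t = p.table
    keep = (t["tss_distance_bp"] >= 0) & (t["tss_distance_bp"] <= max_distance_bp)
    return PromoterMap(t[keep].reset_index(drop=True))


def preprocess_all(
    mrna: OmicsMatrix,
    mirna: OmicsMatrix,
    meth: OmicsMatrix,
    promoter_map: PromoterMap,
    max_bad_fraction: float = 0.20,
    tss_window_bp: int = 1500,
    beta_floor: float = 1e-3,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, PromoterMap, FilterReport]:
    """Run the fixed preprocessing order on all three omics.

    Per omic: feature filter, then sample filter; then the cross-omic sample
    intersection; then size-factor normalisation of the two count matrices
    and median imputation + clamping of the beta matrix; finally the promoter
    map is restricted to the TSS window.
    """
    report = FilterReport()
    filtered = []
    for m in (mrna, mirna, meth):
        name = m.kind.value
        report.n_features_before[name] = m.n_features
        report.n_samples_before[name] = m.n_samples
        m2, feats_gone = filter_features(m, max_bad_fraction)
        m3, samps_gone = filter_samples(m2, max_bad_fraction)
        report.features_removed[name] = feats_gone
        report.samples_removed[name] = samps_gone
        report.n_features_after[name] = m3.n_features
        filtered.append(m3)
    filtered = intersect_samples(filtered)
    for m in filtered:
        report.n_samples_after[m.kind.value] = m.n_samples
    report.samples_retained = list(filtered[0].sample_ids)

    mrna_f, mirna_f, meth_f = filtered
    mrna_n, sf_mrna = size_factor_normalize(mrna_f)
    mirna_n, sf_mirna = size_factor_normalize(mirna_f)
    report.size_factors["mrna_counts"] = dict(zip(mrna_n.sample_ids, sf_mrna))
    report.size_factors["mirna_counts"] = dict(zip(mirna_n.sample_ids, sf_mirna))
    meth_n = impute_and_clamp_beta(meth_f, beta_floor)
    pmap = restrict_promoter_map(promoter_map, tss_window_bp)
    return mrna_n, mirna_n, meth_n, pmap, report
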