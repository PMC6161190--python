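"""Differential abundance between brain regions.

The quantification model follows standard label-free proteomics practice:
per-run median normalisation in log space, an ArcSinH variance-stabilising
transform, one-way ANOVA across regions on transformed values, pairwise
Welch contrasts with Benjamini-Hochberg adjustment, Z-scored regional
profiles, and a three-part significance rule for calling a protein
differentially expressed (DE) in a region: adjusted p below ``alpha``,
at least ``min_peptides`` unique peptides, and a fold change beyond a
multiplicative threshold.

Fold changes are ratios of *raw* (normalised, untransformed) group means;
all test statistics are computed on ArcSinH-transformed values.  The two
scales are deliberately kept separate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceTensor",
    "arcsinh_transform",
    "normalize_runs",
    "group_stats",
    "anova_and_pairwise",
    "bh_adjust",
    "zscore_profile",
    "de_filter",
    "DEFilterResult",
]


@dataclass
class AbundanceTensor:
    """Positive protein intensities indexed by (protein, region, replicate).

    Parameters
    ----------
    intensities : ndarray, shape (n_proteins, n_regions, n_replicates)
        Strictly positive summed peptide-ion intensities.
    proteins : list of str
        Protein identifiers, unique.
    regions : list of str
        Brain-region names.
    replicates : list of str
        Individual-animal (brain) identifiers; replicate ``k`` of every
        region comes from the same animal.
    n_unique_peptides : ndarray of int, shape (n_proteins,)
        Unique peptides used for quantification, ``>= 1``.
    """

    intensities: np.ndarray
    proteins: list[str]
    regions: list[str]
    replicates: list[str]
    n_unique_peptides: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.n_unique_peptides = np.asarray(self.n_unique_peptides, dtype=int)
        P, R, B = self.intensities.shape
        if P != len(self.proteins) or R != len(self.regions) or B != len(self.replicates):
            raise ValueError("intensity array shape does not match axis labels")
        if len(set(self.proteins)) != P:
            raise ValueError("duplicate protein identifiers")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity encountered")
        if np.any(self.intensities <= 0):
            p, r, b = np.argwhere(self.intensities <= 0)[0]
            raise ValueError(
                f"non-positive intensity for protein {self.proteins[p]!r}, "
                f"region {self.regions[r]!r}, replicate {self.replicates[b]!r}"
            )
        if np.any(self.n_unique_peptides < 1):
            raise ValueError("unique peptide counts must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def region_means(self) -> pd.DataFrame:
        """Per-(protein, region) mean raw intensity, proteins x regions."""
        return pd.DataFrame(
            self.intensities.mean(axis=2), index=self.proteins, columns=self.regions
        )

    def arcsinh_region_means(self) -> pd.DataFrame:
        """Per-(protein, region) mean of ArcSinH-transformed intensities."""
        return pd.DataFrame(
            arcsinh_transform(self.intensities).mean(axis=2),
            index=self.proteins,
            columns=self.regions,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: protein_id, n_unique_peptides, then ``<REGION>_<k>`` columns."""
        P, R, B = self.shape
        data = {"protein_id": self.proteins, "n_unique_peptides": self.n_unique_peptides}
        for r, region in enumerate(self.regions):
            for b, rep in enumerate(self.replicates):
                data[f"{region}_{rep}"] = self.intensities[:, r, b]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTensor":
        """Inverse of :meth:`to_frame`; validates the schema."""
        if "protein_id" not in df.columns or "n_unique_peptides" not in df.columns:
            raise ValueError("abundance table needs protein_id and n_unique_peptides columns")
        value_cols = [c for c in df.columns if c not in ("protein_id", "n_unique_peptides")]
        regions: list[str] = []
        replicates: list[str] = []
        for c in value_cols:
            if "_" not in c:
                raise ValueError(f"intensity column {c!r} is not of the form <REGION>_<replicate>")
            region, rep = c.rsplit("_", 1)
            if region not in regions:
                regions.append(region)
            if rep not in replicates:
                replicates.append(rep)
        arr = np.empty((len(df), len(regions), len(replicates)))
        for r, region in enumerate(regions):
            for b, rep in enumerate(replicates):
                col = f"{region}_{rep}"
                if col not in df.columns:
                    raise ValueError(f"missing intensity column {col!r}")
                arr[:, r, b] = df[col].to_numpy(dtype=float)
        return cls(
            intensities=arr,
            proteins=list(df["protein_id"].astype(str)),
            regions=regions,
            replicates=replicates,
            n_unique_peptides=df["n_unique_peptides"].to_numpy(dtype=int),
        )


def arcsinh_transform(x):
    """ArcSinH variance-stabilising transform, ``ln(x + sqrt(x^2 + 1))``.

    Defined at zero (maps to zero) and approximately ``ln(2x)`` for large
    intensities; strictly increasing.
    """
    return np.arcsinh(x)


def normalize_runs(tensor: AbundanceTensor, reference: str | None = None) -> AbundanceTensor:
    """Scale every LC-MS run to the reference run's median log intensity.

    A "run" is one (region, replicate) sample.  Each run is multiplied by
    ``exp(median(log ref) - median(log run))`` so that, after scaling, all
    runs share the reference's median log intensity.  The operation is
    idempotent: normalising an already-normalised tensor changes nothing.

    Parameters
    ----------
    tensor : AbundanceTensor
    reference : str, optional
        Run identifier ``"<REGION>_<replicate>"``.  Defaults to the first
        run in column order.
    """
    P, R, B = tensor.shape
    if P == 0:
        raise ValueError("empty tensor")
    run_ids = [f"{reg}_{rep}" for reg in tensor.regions for rep in tensor.replicates]
    if reference is None:
        reference = run_ids[0]
    if reference not in run_ids:
        raise ValueError(f"reference run {reference!r} not found (known runs: {run_ids[:4]}...)")
    log_int = np.log(tensor.intensities)
    medians = np.median(log_int, axis=0)  # (R, B)
    ref_region, ref_rep = reference.rsplit("_", 1)
    r0 = tensor.regions.index(ref_region)
    b0 = tensor.replicates.index(ref_rep)
    scalars = np.exp(medians[r0, b0] - medians)  # per-run multiplicative factor
    return replace(tensor, intensities=tensor.intensities * scalars[None, :, :])


def group_stats(tensor: AbundanceTensor) -> dict:
    """Per-(protein, region) group means and all pairwise fold changes.

    Returns a dict with:

    ``raw_means``
        proteins x regions DataFrame of raw group means.
    ``arcsinh_means``
        proteins x regions DataFrame of ArcSinH group means.
    ``fold_changes``
        DataFrame with one row per (protein, region_a, region_b) ordered
        pair, ``fold_change = mean_raw(a) / mean_raw(b)``.  Satisfies
        ``FC(b, a) = 1 / FC(a, b)`` exactly.
    """
    raw_means = tensor.region_means()
    if (raw_means.to_numpy() <= 0).any():
        raise ValueError("zero or negative group mean: cannot form fold-change ratio")
    arcsinh_means = tensor.arcsinh_region_means()
    rows = []
    m = raw_means.to_numpy()
    for ra, rb in itertools.permutations(range(len(tensor.regions)), 2):
        fc = m[:, ra] / m[:, rb]
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": tensor.proteins,
                    "region_a": tensor.regions[ra],
                    "region_b": tensor.regions[rb],
                    "fold_change": fc,
                }
            )
        )
    return {
        "raw_means": raw_means,
        "arcsinh_means": arcsinh_means,
        "fold_changes": pd.concat(rows, ignore_index=True),
    }


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch two-sample t along the last axis.

    Returns (p, degenerate_flag).  Groups with zero variance in *both*
    samples are degenerate: p = 1.0 when the means coincide (no evidence
    of difference) and p = 0.0 when they differ (infinitely concentrated
    evidence); either way the flag marks the value as not arising from a
    t distribution.
    """
    na, nb = a.shape[-1], b.shape[-1]
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va, vb = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.where(
        degenerate,
        np.where(ma == mb, 1.0, 0.0),
        2 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), np.where(degenerate, 1.0, df)),
    )
    return p, degenerate


def anova_and_pairwise(tensor: AbundanceTensor) -> dict:
    """Omnibus one-way ANOVA and pairwise Welch contrasts on ArcSinH values.

    The omnibus F tests, per protein, whether mean transformed abundance
    differs across regions; pairwise region contrasts use Welch's
    two-sample t (unequal variances).  Proteins whose within-group
    variance vanishes in a contrast are flagged degenerate rather than
    producing NaN.

    Returns a dict with ``omnibus`` (DataFrame: protein_id, F, p,
    degenerate) and ``pairwise`` (DataFrame: protein_id, region_a,
    region_b, p, degenerate; unordered pairs, region_a before region_b in
    tensor order).
    """
    P, R, B = tensor.shape
    if B < 2:
        raise ValueError("need >= 2 replicates per region for variance estimation")
    x = arcsinh_transform(tensor.intensities)  # (P, R, B)

    # omnibus one-way ANOVA, vectorised over proteins
    group_means = x.mean(axis=2)  # (P, R)
    grand = x.mean(axis=(1, 2))  # (P,)
    ssb = B * ((group_means - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((x - group_means[:, :, None]) ** 2).sum(axis=(1, 2))
    dfb, dfw = R - 1, R * (B - 1)
    degenerate_om = ssw == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p_om = np.where(
        degenerate_om,
        np.where(ssb == 0, 1.0, 0.0),
        stats.f.sf(np.where(degenerate_om, 0.0, F), dfb, dfw),
    )
    omnibus = pd.DataFrame(
        {
            "protein_id": tensor.proteins,
            "F": np.where(degenerate_om, np.where(ssb == 0, 0.0, np.inf), F),
            "p": p_om,
            "degenerate": degenerate_om,
        }
    )

    rows = []
    for ra, rb in itertools.combinations(range(R), 2):
        p, degen = _welch_t(x[:, ra, :], x[:, rb, :])
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": tensor.proteins,
                    "region_a": tensor.regions[ra],
                    "region_b": tensor.regions[rb],
                    "p": p,
                    "degenerate": degen,
                }
            )
        )
    return {"omnibus": omnibus, "pairwise": pd.concat(rows, ignore_index=True)}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    ``p_adj(i) = min_{j >= i} p_(j) * m / j`` on the ascending order
    statistics, clipped at 1, returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def zscore_profile(values) -> tuple[np.ndarray, bool]:
    """Z-score a per-region profile with sample (n-1) standard deviation.

    Returns ``(z, degenerate)``.  A constant profile has no scale; it is
    returned as all zeros with ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector of >= 2 regions")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


@dataclass
class DEFilterResult:
    """Outcome of the differential-expression significance rules."""

    table: pd.DataFrame  # protein_id, region, fold_change, p_adj, n_unique_peptides, direction
    per_region: dict[str, set] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    de_proteins: set = field(default_factory=set)

    @property
    def n_de(self) -> int:
        return len(self.de_proteins)


def de_filter(
    tensor: AbundanceTensor,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    min_peptides: int = 2,
    mode: str = "all",
    stats_cache: dict | None = None,
) -> DEFilterResult:
    """Call differentially expressed proteins per region.

    A protein is DE *up* in region ``r`` when its fold change against
    comparison regions is ``>= fold_threshold`` (or ``<= 1/fold_threshold``
    for *down*), the BH-adjusted pairwise p-values are below ``alpha``,
    and it was quantified with ``>= min_peptides`` unique peptides.
    Adjustment is applied across proteins within each region-pair
    contrast.

    Parameters
    ----------
    mode : {"all", "any"}
        ``"all"`` (default) requires the fold and significance rules
        against *every* other region — the protein stands out from all
        comparison regions in a consistent direction.  ``"any"`` requires
        a single qualifying contrast.
    stats_cache : dict, optional
        Output of :func:`group_stats`/:func:`anova_and_pairwise` to avoid
        recomputation: keys ``raw_means`` and ``pairwise``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    P, R, B = tensor.shape
    if stats_cache is None:
        stats_cache = {}
    raw_means = stats_cache.get("raw_means")
    if raw_means is None:
        raw_means = tensor.region_means()
    pairwise = stats_cache.get("pairwise")
    if pairwise is None:
        pairwise = anova_and_pairwise(tensor)["pairwise"]

    # BH within each contrast, across proteins
    pairwise = pairwise.copy()
    pairwise["p_adj"] = np.nan
    for (_, _), idx in pairwise.groupby(["region_a", "region_b"]).groups.items():
        pairwise.loc[idx, "p_adj"] = bh_adjust(pairwise.loc[idx, "p"].to_numpy())

    # p_adj lookup as (P, R, R) symmetric array
    padj = np.ones((P, R, R))
    prot_index = {p: i for i, p in enumerate(tensor.proteins)}
    reg_index = {r: i for i, r in enumerate(tensor.regions)}
    pi = pairwise["protein_id"].map(prot_index).to_numpy()
    ra = pairwise["region_a"].map(reg_index).to_numpy()
    rb = pairwise["region_b"].map(reg_index).to_numpy()
    padj[pi, ra, rb] = pairwise["p_adj"].to_numpy()
    padj[pi, rb, ra] = pairwise["p_adj"].to_numpy()

    m = raw_means.to_numpy()  # (P, R)
    with np.errstate(divide="ignore"):
        fc = m[:, :, None] / m[:, None, :]  # fc[p, r, r'] = mean(r)/mean(r')

    peptide_ok = tensor.n_unique_peptides >= min_peptides  # (P,)
    other = ~np.eye(R, dtype=bool)

    rows = []
    per_region: dict[str, set] = {reg: set() for reg in tensor.regions}
    for r in range(R):
        oth = other[r]
        up_fold = fc[:, r, oth] >= fold_threshold
        down_fold = fc[:, r, oth] <= 1.0 / fold_threshold
        sig = padj[:, r, oth] < alpha
        if mode == "all":
            up = up_fold.all(axis=1) & sig.all(axis=1)
            down = down_fold.all(axis=1) & sig.all(axis=1)
        else:
            up = (up_fold & sig).any(axis=1)
            down = (down_fold & sig).any(axis=1)
        called = (up | down) & peptide_ok
        for p in np.nonzero(called)[0]:
            direction = "up" if up[p] else "down"
            sub = fc[p, r, oth]
            extreme = sub.max() if direction == "up" else sub.min()
            rows.append(
                {
                    "protein_id": tensor.proteins[p],
                    "region": tensor.regions[r],
                    "direction": direction,
                    "fold_change": extreme,
                    "max_p_adj": padj[p, r, oth].max() if mode == "all" else padj[p, r, oth].min(),
                    "n_unique_peptides": int(tensor.n_unique_peptides[p]),
                }
            )
            per_region[tensor.regions[r]].add(tensor.proteins[p])

    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "region",
            "direction",
            "fold_change",
            "max_p_adj",
            "n_unique_peptides",
        ],
    )
    de_proteins = set().union(*per_region.values()) if per_region else set()
    counts = {reg: len(s) for reg, s in per_region.items()}
    counts["union"] = len(de_proteins)
    return DEFilterResult(
        table=table, per_region=per_region, counts=counts, de_proteins=de_proteins
    )
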