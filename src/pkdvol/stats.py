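"""Agreement and similarity statistics between automated and reference
segmentations and total kidney volumes.

Implements the full battery used to validate automated TKV pipelines:
Dice similarity coefficient (spatial overlap), Lin's concordance
correlation coefficient with a Fisher-z confidence interval, Bland-Altman
limits of agreement in absolute and percentage form, the repeated-measures
coefficient of variation, signed and absolute percentage errors, RMSE and
RMSPE, Spearman rank correlation, and the Wilcoxon signed-rank test.  The
sign convention throughout is automated minus true.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PairedTKV:
    case_id: str
    tkv_true_ml: float
    tkv_auto_ml: float

    def __post_init__(self) -> None:
        if self.tkv_true_ml < 0 or self.tkv_auto_ml < 0:
            raise ValueError("TKV values must be >= 0")


@dataclass
class AgreementReport:
    """All agreement statistics for one cohort comparison."""

    n_cases: int
    dsc_mean: float
    dsc_sd: float
    ccc: float
    ccc_ci95: tuple[float, float]
    ba_mean_diff_ml: float
    ba_loa_ml: tuple[float, float]
    ba_mean_pct_diff: float
    ba_loa_pct: tuple[float, float]
    cov_pct: float
    mpe_pct: float
    mpe_sd: float
    mape_pct: float
    mape_sd: float
    rmse_ml: float
    rmspe_pct: float
    spearman_rho: float
    spearman_p: float
    wilcoxon_p: float
    per_case: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def summary(self) -> dict[str, float]:
        d = {k: v for k, v in self.__dict__.items() if k != "per_case"}
        d["ccc_ci95_low"], d["ccc_ci95_high"] = d.pop("ccc_ci95")
        d["ba_loa_ml_low"], d["ba_loa_ml_high"] = d.pop("ba_loa_ml")
        d["ba_loa_pct_low"], d["ba_loa_pct_high"] = d.pop("ba_loa_pct")
        return d


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Two empty masks agree perfectly: DSC = 1.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


def ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a 95% CI.

    CCC = 2*cov(x,y) / (var x + var y + (mean x - mean y)^2), using
    population (1/n) moments.  The CI applies Lin's asymptotic standard
    error on the Fisher z scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal-length series with n >= 3")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()          # population moments
    sxy = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return np.nan, (np.nan, np.nan)
    c = 2.0 * sxy / denom
    if vx == 0 or vy == 0:
        return c, (np.nan, np.nan)
    r = sxy / np.sqrt(vx * vy)
    if abs(c) >= 1.0 or r == 0:
        return c, (c, c)
    u2 = (mx - my) ** 2 / np.sqrt(vx * vy)
    se_z = np.sqrt(
        ((1 - r ** 2) * c ** 2 / ((1 - c ** 2) * r ** 2)
         + 2 * c ** 3 * (1 - c) * u2 / (r * (1 - c ** 2) ** 2)
         - c ** 4 * u2 ** 2 / (2 * r ** 2 * (1 - c ** 2) ** 2)) / (n - 2))
    zc = np.arctanh(c)
    q = sps.norm.ppf(1 - alpha / 2)
    return c, (float(np.tanh(zc - q * se_z)), float(np.tanh(zc + q * se_z)))


def bland_altman(pairs: list[PairedTKV], mode: str = "absolute"
                 ) -> tuple[float, tuple[float, float]]:
    """Bland-Altman mean difference and 95% limits of agreement.

    ``mode='absolute'``: differences auto - true in mL.
    ``mode='percentage'``: 100*(auto - true) / pairwise mean; pairs with a
    zero pairwise mean are excluded with a warning.
    LOA = mean +/- 1.96 * SD (sample SD, n-1).
    """
    if mode not in ("absolute", "percentage"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    auto = np.array([p.tkv_auto_ml for p in pairs], dtype=float)
    true = np.array([p.tkv_true_ml for p in pairs], dtype=float)
    if mode == "absolute":
        diffs = auto - true
    else:
        means = (auto + true) / 2.0
        keep = means != 0
        if not np.all(keep):
            import warnings
            warnings.warn(f"excluding {np.count_nonzero(~keep)} pair(s) with "
                          "zero pairwise mean from percentage Bland-Altman",
                          stacklevel=2)
        diffs = 100.0 * (auto[keep] - true[keep]) / means[keep]
        if diffs.size < 2:
            raise ValueError("fewer than 2 usable pairs in percentage mode")
    m = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return m, (m - 1.96 * sd, m + 1.96 * sd)


def cov_repeated(pairs: list[PairedTKV]) -> float:
    """Repeated-measures coefficient of variation, percent.

    Within-pair root-mean-square SD over the grand mean of all
    measurements: 100 * sqrt(mean_i var_i) / grand_mean, with the per-pair
    sample variance (a - b)^2 / 2.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    auto = np.array([p.tkv_auto_ml for p in pairs], dtype=float)
    true = np.array([p.tkv_true_ml for p in pairs], dtype=float)
    grand = np.concatenate([auto, true]).mean()
    if grand == 0:
        raise ValueError("grand mean is zero; COV undefined")
    within_var = (auto - true) ** 2 / 2.0
    return float(100.0 * np.sqrt(within_var.mean()) / grand)


def error_metrics(pairs: list[PairedTKV]) -> dict[str, float]:
    """Signed/absolute percentage errors, RMSE (mL) and RMSPE (%).

    pe_i = 100*(auto_i - true_i)/true_i; MPE = mean(pe); MAPE = mean|pe|;
    RMSE on raw mL differences; RMSPE = sqrt(mean(pe^2)).  SDs are sample
    (n-1) SDs of pe and |pe|.
    """
    auto = np.array([p.tkv_auto_ml for p in pairs], dtype=float)
    true = np.array([p.tkv_true_ml for p in pairs], dtype=float)
    if np.any(true <= 0):
        raise ValueError("percentage errors require true TKV > 0 for all cases")
    pe = 100.0 * (auto - true) / true
    ddof = 1 if pe.size > 1 else 0
    return dict(
        mpe=float(pe.mean()),
        mpe_sd=float(pe.std(ddof=ddof)),
        mape=float(np.abs(pe).mean()),
        mape_sd=float(np.abs(pe).std(ddof=ddof)),
        rmse=float(np.sqrt(((auto - true) ** 2).mean())),
        rmspe=float(np.sqrt((pe ** 2).mean())),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need two equal-length series with n >= 3")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 remaining pairs, a normal approximation with continuity
    correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return float("nan")
    method = "exact" if d.size <= 25 else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def evaluate_cohort(predictions: list, references: list) -> AgreementReport:
    """Assemble the full agreement battery for matched case lists.

    Each element must expose ``case_id``, a binary ``mask`` and
    ``tkv_ml`` (for predictions this is the automated volumetry; for
    references the ground-truth volumetry).  Cases are matched by id.
    """
    pred_by_id = {p.case_id: p for p in predictions}
    ref_by_id = {r.case_id: r for r in references}
    missing = sorted(set(pred_by_id) ^ set(ref_by_id))
    if missing:
        raise ValueError(f"unmatched case ids: {missing}")
    ids = sorted(pred_by_id)
    rows = []
    pairs = []
    for cid in ids:
        p, r = pred_by_id[cid], ref_by_id[cid]
        d = dice(p.mask, r.mask)
        pairs.append(PairedTKV(cid, r.tkv_ml, p.tkv_ml))
        rows.append(dict(case_id=cid, dsc=d, tkv_true_ml=r.tkv_ml,
                         tkv_auto_ml=p.tkv_ml,
                         pct_error=100.0 * (p.tkv_ml - r.tkv_ml) / r.tkv_ml
                         if r.tkv_ml > 0 else np.nan))
    per_case = pd.DataFrame(rows)
    auto = per_case["tkv_auto_ml"].to_numpy()
    true = per_case["tkv_true_ml"].to_numpy()
    dscs = per_case["dsc"].to_numpy()
    c, ci = ccc(true, auto)
    ba_ml, loa_ml = bland_altman(pairs, "absolute")
    ba_pct, loa_pct = bland_altman(pairs, "percentage")
    err = error_metrics(pairs)
    rho, rho_p = spearman(true, auto)
    ddof = 1 if len(ids) > 1 else 0
    return AgreementReport(
        n_cases=len(ids),
        dsc_mean=float(dscs.mean()), dsc_sd=float(dscs.std(ddof=ddof)),
        ccc=c, ccc_ci95=ci,
        ba_mean_diff_ml=ba_ml, ba_loa_ml=loa_ml,
        ba_mean_pct_diff=ba_pct, ba_loa_pct=loa_pct,
        cov_pct=cov_repeated(pairs),
        mpe_pct=err["mpe"], mpe_sd=err["mpe_sd"],
        mape_pct=err["mape"], mape_sd=err["mape_sd"],
        rmse_ml=err["rmse"], rmspe_pct=err["rmspe"],
        spearman_rho=rho, spearman_p=rho_p,
        wilcoxon_p=wilcoxon_signed_rank(auto, true),
        per_case=per_case,
    )


def crossval_partition(tkv_by_case: dict[str, float], k: int = 3,
                       seed: int = 0) -> list[list[str]]:
    """TKV-stratified k-fold partition.

    Cases are sorted by ascending TKV; each consecutive block of k cases is
    dealt randomly, one to each fold, so every fold samples the full TKV
    range uniformly.  A final partial block is dealt to distinct random
    folds.  Fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(tkv_by_case)
    if n < k:
        raise ValueError(f"need at least k={k} cases, got {n}")
    rng = np.random.default_rng(seed)
    ordered = sorted(tkv_by_case, key=lambda c: (tkv_by_case[c], c))
    folds: list[list[str]] = [[] for _ in range(k)]
    for start in range(0, n, k):
        block = ordered[start:start + k]
        dest = rng.permutation(k)[:len(block)]
        for cid, f in zip(block, dest):
            folds[f].append(cid)
    return folds
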