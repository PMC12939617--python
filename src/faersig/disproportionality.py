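"""Four-algorithm disproportionality screening with consensus signal flags.

Each drug–event pair is summarised by the 2×2 contingency table

====  =========================  =========================
..    cataract PT                other reactions
====  =========================  =========================
drug  a                          b
rest  c                          d
====  =========================  =========================

against the deduplicated pediatric background (N = a+b+c+d).  Four
complementary statistics are computed:

* **ROR** — reporting odds ratio ad/(bc), Wald 95% CI on the log scale;
  signal when a >= 3 and the CI lower bound exceeds 1.
* **PRR** — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with its Wald
  CI, plus the Yates-corrected chi-square
  N(|ad−bc|−N/2)² / [(a+b)(c+d)(a+c)(b+d)] clamped at zero; signal when
  a >= 3 and chi-square > 4.
* **BCPNN IC** — information component log2[aN/((a+b)(a+c))] with the
  Bayesian posterior moments E(IC), V(IC) under Dirichlet-style priors
  (alpha1=beta1=1, alpha=beta=2, gamma11=1, gamma derived per table);
  signal when E(IC) > 0 (an optional strict mode flags on IC−2SD > 0,
  the IC025-style criterion).
* **EBGM** — here the unshrunk relative reporting ratio aN/((a+b)(a+c))
  with EBGM05 = exp(ln EBGM − 1.95·sqrt(1/a+1/b+1/c+1/d)); signal when
  a > 0 and EBGM05 > 2.  This is *not* DuMouchel's gamma-mixture MGPS;
  see docs/methods.md.

A **consensus signal** requires all four criteria simultaneously; any
statistic undefined because of a zero cell counts as not flagged (no
continuity correction is applied anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

Z95 = 1.96
EBGM05_MULTIPLIER = 1.95  # lower-bound multiplier used with EBGM


class ContingencyError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts a, b, c, d; N = a+b+c+d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ContingencyError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class BcpnnPriors:
    """Dirichlet-style prior counts for the BCPNN information component."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


# ---------------------------------------------------------------------------
# vectorised cores (work on numpy arrays; scalar wrappers below)
# ---------------------------------------------------------------------------

def _asf(x):
    return np.asarray(x, dtype=float)


def ror_arrays(a, b, c, d):
    """ROR point estimate and Wald 95% CI; NaN wherever a cell is zero."""
    a, b, c, d = map(_asf, (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(est) - Z95 * se)
        hi = np.exp(np.log(est) + Z95 * se)
    bad = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    est = np.where(bad, np.nan, est)
    lo = np.where(bad, np.nan, lo)
    hi = np.where(bad, np.nan, hi)
    return est, lo, hi


def prr_arrays(a, b, c, d):
    """PRR point estimate and Wald 95% CI; NaN wherever a cell is zero."""
    a, b, c, d = map(_asf, (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (a / (a + b)) / (c / (c + d))
        se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        lo = np.exp(np.log(est) - Z95 * se)
        hi = np.exp(np.log(est) + Z95 * se)
    bad = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    est = np.where(bad, np.nan, est)
    lo = np.where(bad, np.nan, lo)
    hi = np.where(bad, np.nan, hi)
    return est, lo, hi


def yates_chi2_arrays(a, b, c, d):
    """Yates-corrected chi-square, clamped at 0 when N/2 >= |ad−bc|."""
    a, b, c, d = map(_asf, (a, b, c, d))
    n = a + b + c + d
    num = np.maximum(np.abs(a * d - b * c) - n / 2.0, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * num**2 / denom
    return np.where(denom == 0, np.nan, chi2)


def bcpnn_arrays(a, b, c, d, priors: BcpnnPriors = BcpnnPriors()):
    """Raw IC, E(IC), V(IC) and IC−2SD for the BCPNN.

    The raw IC is log2[aN/((a+b)(a+c))] (−inf when a = 0); the posterior
    moments are always defined thanks to the priors, with the per-table
    normaliser gamma = gamma11·(N+alpha)(N+beta)/[(a+b+alpha1)(a+c+beta1)].
    """
    a, b, c, d = map(_asf, (a, b, c, d))
    n = a + b + c + d
    p = priors
    with np.errstate(divide="ignore", invalid="ignore"):
        ic_raw = np.log2(a * n / ((a + b) * (a + c)))
        gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
            (a + b + p.alpha1) * (a + c + p.beta1)
        )
        e_ic = np.log2(
            (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
            / ((n + gamma) * (a + b + p.alpha1) * (a + c + p.beta1))
        )
        v_ic = (
            (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
            + (n - (a + b) + p.alpha - p.alpha1)
            / ((a + b + p.alpha1) * (1 + n + p.alpha))
            + (n - (a + c) + p.beta - p.beta1)
            / ((a + c + p.beta1) * (1 + n + p.beta))
        ) / np.log(2.0) ** 2
        ic_2sd = e_ic - 2.0 * np.sqrt(v_ic)
    return ic_raw, e_ic, v_ic, ic_2sd


def ebgm_arrays(a, b, c, d):
    """EBGM (relative reporting ratio) and EBGM05; EBGM05 NaN on zero cells."""
    a, b, c, d = map(_asf, (a, b, c, d))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        ebgm = a * n / ((a + c) * (a + b))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ebgm05 = np.exp(np.log(ebgm) - EBGM05_MULTIPLIER * se)
    degenerate = ((a + b) == 0) | ((a + c) == 0)
    ebgm = np.where(degenerate, np.nan, ebgm)
    bad = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    ebgm05 = np.where(bad, np.nan, ebgm05)
    return ebgm, ebgm05


def point_from_wald_ci(lower: float, upper: float) -> float:
    """Recover a Wald point estimate from its 95% CI bounds.

    Wald intervals for ratio measures are symmetric on the log scale, so the
    geometric mean of the bounds equals the point estimate — the bridge used
    to check published ROR/CI triples for internal consistency.
    """
    return float(np.exp((np.log(float(lower)) + np.log(float(upper))) / 2.0))


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RorResult:
    estimate: float
    ci: tuple[float, float]
    flag: bool
    reason: str = ""


@dataclass(frozen=True)
class PrrResult:
    estimate: float
    ci: tuple[float, float]
    chi2: float
    flag: bool
    reason: str = ""


@dataclass(frozen=True)
class BcpnnResult:
    ic: float
    e_ic: float
    v_ic: float
    ic_minus_2sd: float
    flag: bool
    strict_flag: bool


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    ebgm05: float
    flag: bool
    reason: str = ""


def ror(table: ContingencyTable) -> RorResult:
    """Reporting odds ratio; signal iff a >= 3 and CI lower bound > 1."""
    est, lo, hi = (float(x) for x in ror_arrays(*table.as_tuple()))
    if np.isnan(est):
        return RorResult(np.nan, (np.nan, np.nan), False, "zero cell")
    return RorResult(est, (lo, hi), bool(table.a >= 3 and lo > 1.0))


def prr(table: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio; signal iff a >= 3 and chi-square > 4."""
    est, lo, hi = (float(x) for x in prr_arrays(*table.as_tuple()))
    chi2 = float(yates_chi2_arrays(*table.as_tuple()))
    if np.isnan(est):
        return PrrResult(np.nan, (np.nan, np.nan), chi2, False, "zero cell")
    return PrrResult(est, (lo, hi), chi2, bool(table.a >= 3 and chi2 > 4.0))


def bcpnn_ic(table: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()) -> BcpnnResult:
    """BCPNN information component; signal iff E(IC) > 0."""
    ic_raw, e_ic, v_ic, ic_2sd = (
        float(x) for x in bcpnn_arrays(*table.as_tuple(), priors=priors)
    )
    return BcpnnResult(ic_raw, e_ic, v_ic, ic_2sd, bool(e_ic > 0.0), bool(ic_2sd > 0.0))


def ebgm(table: ContingencyTable) -> EbgmResult:
    """EBGM (as the relative reporting ratio); signal iff a > 0 and EBGM05 > 2."""
    e, e05 = (float(x) for x in ebgm_arrays(*table.as_tuple()))
    if np.isnan(e05):
        return EbgmResult(e, np.nan, False, "zero cell")
    return EbgmResult(e, e05, bool(table.a > 0 and e05 > 2.0))


@dataclass(frozen=True)
class SignalRow:
    """Per-drug results of all four algorithms plus consensus flag."""

    entity: str
    table: ContingencyTable
    ror: RorResult
    prr: PrrResult
    bcpnn: BcpnnResult
    ebgm: EbgmResult
    bcpnn_strict: bool = False

    @property
    def flags(self) -> dict[str, bool]:
        bflag = self.bcpnn.strict_flag if self.bcpnn_strict else self.bcpnn.flag
        return {
            "ror_flag": self.ror.flag,
            "prr_flag": self.prr.flag,
            "bcpnn_flag": bflag,
            "mgps_flag": self.ebgm.flag,
        }

    @property
    def consensus_flag(self) -> bool:
        return all(self.flags.values())


def evaluate_signal(
    entity: str,
    table: ContingencyTable,
    priors: BcpnnPriors = BcpnnPriors(),
    bcpnn_strict: bool = False,
) -> SignalRow:
    """All four statistics for one drug; consensus = conjunction of flags."""
    return SignalRow(
        entity=entity,
        table=table,
        ror=ror(table),
        prr=prr(table),
        bcpnn=bcpnn_ic(table, priors),
        ebgm=ebgm(table),
        bcpnn_strict=bcpnn_strict,
    )


# ---------------------------------------------------------------------------
# dataset-level screening
# ---------------------------------------------------------------------------

def _case_col(query) -> str:
    name = query if isinstance(query, str) else query.name
    if name not in ("broad", "narrow"):
        raise ValueError(f"query must be broad or narrow, got {name!r}")
    return f"is_case_{name}"


def build_contingency(
    dataset: pd.DataFrame, drug: str, query="broad", background: str = "all"
) -> ContingencyTable:
    """Count the 2×2 table for one drug against the pediatric background.

    ``background="all"`` uses every deduplicated pediatric report for the
    margins (the default convention); ``"ps_assigned"`` restricts N to
    reports with an assigned Primary-Suspect drug.
    """
    df = dataset
    if background == "ps_assigned":
        df = df[df["ps_entity"].notna()]
    elif background != "all":
        raise ValueError("background must be 'all' or 'ps_assigned'")
    case = df[_case_col(query)].to_numpy(dtype=bool)
    exposed = (df["ps_entity"] == drug).to_numpy(dtype=bool)
    a = int((exposed & case).sum())
    b = int((exposed & ~case).sum())
    c = int((~exposed & case).sum())
    d = int((~exposed & ~case).sum())
    return ContingencyTable(a, b, c, d)


def screen(
    dataset: pd.DataFrame,
    query="broad",
    min_reports: int = 3,
    drugs: Optional[Sequence[str]] = None,
    priors: BcpnnPriors = BcpnnPriors(),
    bcpnn_strict: bool = False,
    background: str = "all",
) -> pd.DataFrame:
    """One row per drug with a >= ``min_reports``, sorted by descending ROR.

    Ties in the sort are broken by larger a, then lexicographic entity name.
    Returns a DataFrame with counts, all four statistics, per-algorithm
    flags and the consensus flag.
    """
    df = dataset
    if background == "ps_assigned":
        df = df[df["ps_entity"].notna()]
    case_col = _case_col(query)
    n_total = len(df)
    n_cases = int(df[case_col].sum())

    grp = df[df["ps_entity"].notna()].groupby("ps_entity", sort=True)
    counts = grp.agg(
        exposed=("ps_entity", "size"), a=(case_col, "sum")
    ).reset_index()
    counts["a"] = counts["a"].astype(int)
    if drugs is not None:
        counts = counts[counts["ps_entity"].isin(set(drugs))]
    counts = counts[counts["a"] >= min_reports]

    a = counts["a"].to_numpy(dtype=int)
    b = counts["exposed"].to_numpy(dtype=int) - a
    c = n_cases - a
    d = n_total - counts["exposed"].to_numpy(dtype=int) - c

    ror_est, ror_lo, ror_hi = ror_arrays(a, b, c, d)
    prr_est, prr_lo, prr_hi = prr_arrays(a, b, c, d)
    chi2 = yates_chi2_arrays(a, b, c, d)
    ic_raw, e_ic, v_ic, ic_2sd = bcpnn_arrays(a, b, c, d, priors=priors)
    ebgm_est, ebgm05 = ebgm_arrays(a, b, c, d)

    with np.errstate(invalid="ignore"):
        ror_flag = (a >= 3) & (ror_lo > 1.0)
        prr_flag = (a >= 3) & (chi2 > 4.0)
        bcpnn_flag = (ic_2sd > 0.0) if bcpnn_strict else (e_ic > 0.0)
        mgps_flag = (a > 0) & (ebgm05 > 2.0)
    ror_flag = np.where(np.isnan(ror_lo), False, ror_flag).astype(bool)
    prr_flag = np.where(np.isnan(chi2), False, prr_flag).astype(bool)
    mgps_flag = np.where(np.isnan(ebgm05), False, mgps_flag).astype(bool)
    consensus = ror_flag & prr_flag & bcpnn_flag & mgps_flag

    out = pd.DataFrame(
        {
            "entity": counts["ps_entity"].to_numpy(),
            "a": a, "b": b, "c": c, "d": d,
            "ror": ror_est, "ror_low": ror_lo, "ror_high": ror_hi,
            "prr": prr_est, "prr_low": prr_lo, "prr_high": prr_hi,
            "chi2": chi2,
            "ic": ic_raw, "e_ic": e_ic, "v_ic": v_ic, "ic_minus_2sd": ic_2sd,
            "ebgm": ebgm_est, "ebgm05": ebgm05,
            "log10_ror": np.log10(ror_est),
            "ror_flag": ror_flag, "prr_flag": prr_flag,
            "bcpnn_flag": bcpnn_flag, "mgps_flag": mgps_flag,
            "consensus": consensus,
        }
    )
    sort_key = np.where(np.isnan(out["ror"].to_numpy()), -np.inf, out["ror"].to_numpy())
    out = (
        out.assign(_k=sort_key)
        .sort_values(["_k", "a", "entity"], ascending=[False, False, True], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    return out


class DisproportionalityScreen:
    """Model-style interface: build from the analysis dataset, then fit.

    Parameters
    ----------
    dataset : DataFrame from :func:`faersig.preprocess.prepare_dataset`.
    query : "broad" | "narrow" | PtQuerySet — event definition.
    min_reports : minimum a for a drug to be reported (default 3).
    bcpnn_strict : flag BCPNN on IC−2SD > 0 instead of E(IC) > 0.
    background : "all" (every pediatric report) or "ps_assigned".
    """

    def __init__(
        self,
        dataset: pd.DataFrame,
        query="broad",
        min_reports: int = 3,
        priors: BcpnnPriors = BcpnnPriors(),
        bcpnn_strict: bool = False,
        background: str = "all",
    ):
        self.dataset = dataset
        self.query = query
        self.min_reports = min_reports
        self.priors = priors
        self.bcpnn_strict = bcpnn_strict
        self.background = background

    def fit(self) -> "ScreenResults":
        table = screen(
            self.dataset,
            query=self.query,
            min_reports=self.min_reports,
            priors=self.priors,
            bcpnn_strict=self.bcpnn_strict,
            background=self.background,
        )
        return ScreenResults(self, table)


@dataclass
class ScreenResults:
    """Per-drug statistics, flags and the consensus signal list."""

    model: DisproportionalityScreen
    table: pd.DataFrame

    @property
    def signals(self) -> list[str]:
        return list(self.table.loc[self.table["consensus"], "entity"])

    def summary(self, top: Optional[int] = None) -> pd.DataFrame:
        cols = [
            "entity", "a", "ror", "ror_low", "ror_high", "prr", "chi2",
            "e_ic", "ic_minus_2sd", "ebgm", "ebgm05", "consensus",
        ]
        df = self.table[cols]
        return df.head(top) if top else df

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)
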