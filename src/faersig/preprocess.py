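"""From raw quarter bundles to the deduplicated pediatric analysis dataset.

Steps, in pipeline order:

1. **Deduplication** — spontaneous reports arrive as CASEID-versioned
   updates; per case we keep the version with the latest FDA receipt date
   (FDA_DT), ties broken by the largest PRIMARYID.
2. **Age standardisation** — AGE comes in mixed units (AGE_COD one of
   YR/MON/WK/DY/DEC); everything is converted to years.  Unknown codes and
   negative values map to missing.
3. **Pediatric filter** — strictly 0 < age < 18 years; missing ages drop.
4. **Primary-Suspect drug** — among a report's DRUG rows with role code PS,
   the one with the lowest DRUG_SEQ defines the report's exposure; reports
   without a PS row are excluded from drug-level analysis.
5. **Time to onset** — EVENT_DT − START_DT in days, with every report
   assigned exactly one category: ok / missing / incomplete / inconsistent /
   implausible.  Partial dates are never imputed.

Comparison conventions: CASEID compares as a string; FDA_DT and PRIMARYID
compare numerically, with non-numeric PRIMARYIDs falling back to
lexicographic order after all numeric ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .case_definition import DrugNameMap, PtQuerySet

#: AGE_COD -> multiplier to years.
AGE_FACTORS: dict[str, float] = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "DEC": 10.0,
}

#: Days beyond which a time to onset is considered implausible (18 years —
#: inert for pediatric subjects, configurable everywhere it is used).
IMPLAUSIBLE_TTO_DAYS = 6574

TTO_CATEGORIES = ("ok", "missing", "incomplete", "inconsistent", "implausible")


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _dedup_sort_keys(df: pd.DataFrame) -> pd.DataFrame:
    fda = pd.to_numeric(df["fda_dt"], errors="coerce").fillna(-1.0)
    pid_str = df["primaryid"].astype(str).str.strip()
    pid_num = pd.to_numeric(pid_str, errors="coerce")
    is_nonnum = pid_num.isna()
    return df.assign(
        _fda=fda.to_numpy(),
        _pid_nonnum=is_nonnum.to_numpy(),  # numeric sorts before non-numeric
        _pid_num=pid_num.fillna(-np.inf).to_numpy(),
        _pid_str=pid_str.to_numpy(),
    )


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per CASEID: latest FDA_DT, ties broken by largest PRIMARYID.

    Rows with a missing CASEID are excluded and counted, not fatal.  The
    result is sorted by CASEID, so the kept set is invariant under any
    permutation of the input.
    """
    caseid = demo["caseid"].astype(str).str.strip()
    missing = caseid == ""
    counts = {"input_rows": len(demo), "missing_caseid": int(missing.sum())}
    df = demo[~missing].copy()
    df["caseid"] = caseid[~missing]
    keyed = _dedup_sort_keys(df)
    keyed = keyed.sort_values(
        ["caseid", "_fda", "_pid_nonnum", "_pid_num", "_pid_str"],
        kind="stable",
    )
    kept = keyed.drop_duplicates(subset="caseid", keep="last")
    kept = kept.drop(columns=["_fda", "_pid_nonnum", "_pid_num", "_pid_str"])
    kept = kept.reset_index(drop=True)
    counts["duplicates_removed"] = len(df) - len(kept)
    counts["kept"] = len(kept)
    return kept, counts


# ---------------------------------------------------------------------------
# age standardisation & pediatric filter
# ---------------------------------------------------------------------------

def standardize_age(age_value, age_code) -> float:
    """Convert one (value, unit-code) pair to years; NaN when unusable."""
    try:
        v = float(age_value)
    except (TypeError, ValueError):
        return float("nan")
    if np.isnan(v) or v < 0:
        return float("nan")
    factor = AGE_FACTORS.get(str(age_code).strip().upper())
    if factor is None:
        return float("nan")
    return v * factor


def standardize_age_series(values: pd.Series, codes: pd.Series) -> pd.Series:
    """Vectorised :func:`standardize_age`."""
    v = pd.to_numeric(values, errors="coerce")
    factor = codes.astype(str).str.strip().str.upper().map(AGE_FACTORS)
    out = v * factor
    out[v < 0] = np.nan
    return out


def filter_pediatric(
    df: pd.DataFrame,
    age_col: str = "age_years",
    lower: float = 0.0,
    upper: float = 18.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain rows with ``lower < age < upper`` (strict); missing age drops."""
    age = df[age_col]
    present = age.notna()
    keep = present & (age > lower) & (age < upper)
    counts = {
        "input_rows": len(df),
        "age_missing": int((~present).sum()),
        "age_out_of_range": int((present & ~keep).sum()),
        "retained": int(keep.sum()),
    }
    return df[keep].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# primary-suspect drug
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuspectDrugAssignment:
    primaryid: str
    verbatim_name: str
    drug_seq: float
    role_code: str = "PS"
    route: str = ""


def select_primary_suspect(
    drug_rows: Iterable[dict], primaryid: str
) -> Optional[SuspectDrugAssignment]:
    """Among a report's PS rows, the one with minimal DRUG_SEQ; None if no PS.

    Non-numeric DRUG_SEQ values order after every numeric one (treated as
    +inf), so they are only selected when no well-formed PS row exists.
    """
    best: Optional[tuple[float, str]] = None
    best_row = None
    for row in drug_rows:
        if str(row.get("role_cod", "")).strip().upper() != "PS":
            continue
        raw_seq = str(row.get("drug_seq", "")).strip()
        try:
            seq = float(raw_seq)
        except ValueError:
            seq = float("inf")
        key = (seq, raw_seq)
        if best is None or key < best:
            best = key
            best_row = row
    if best_row is None:
        return None
    return SuspectDrugAssignment(
        primaryid=str(primaryid),
        verbatim_name=str(best_row.get("drugname", "")),
        drug_seq=best[0],
        route=str(best_row.get("route", "")),
    )


def assign_primary_suspect_frame(drug: pd.DataFrame) -> pd.DataFrame:
    """Vectorised PS selection: one row per PRIMARYID that has a PS row."""
    role = drug["role_cod"].astype(str).str.strip().str.upper()
    ps = drug[role == "PS"].copy()
    seq = pd.to_numeric(ps["drug_seq"], errors="coerce")
    ps["_seq"] = seq.fillna(np.inf)
    ps["_seq_str"] = ps["drug_seq"].astype(str)
    ps = ps.sort_values(["primaryid", "_seq", "_seq_str"], kind="stable")
    out = ps.drop_duplicates(subset="primaryid", keep="first")
    return out.drop(columns=["_seq", "_seq_str"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# time to onset
# ---------------------------------------------------------------------------

def _parse_date8(s: str):
    """A complete 8-digit date or None."""
    s = str(s).strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return pd.Timestamp(year=int(s[:4]), month=int(s[4:6]), day=int(s[6:8]))
    except ValueError:
        return None


def compute_tto_days(
    start_dt, event_dt, implausible_days: int = IMPLAUSIBLE_TTO_DAYS
) -> tuple[Optional[int], str]:
    """Days from therapy start to event onset, or a categorised rejection.

    Returns ``(days, "ok")`` when both dates are complete valid 8-digit
    dates and ``1 <= days <= implausible_days``; otherwise ``(None, reason)``
    with reason one of missing / incomplete / inconsistent / implausible.
    Rejections are data, not errors.
    """
    s = "" if start_dt is None or (isinstance(start_dt, float) and np.isnan(start_dt)) else str(start_dt).strip()
    e = "" if event_dt is None or (isinstance(event_dt, float) and np.isnan(event_dt)) else str(event_dt).strip()
    if s == "" or e == "":
        return None, "missing"
    sd, ed = _parse_date8(s), _parse_date8(e)
    if sd is None or ed is None:
        return None, "incomplete"
    days = (ed - sd).days
    if days <= 0:
        return None, "inconsistent"
    if days > implausible_days:
        return None, "implausible"
    return int(days), "ok"


def compute_tto_series(
    start: pd.Series, event: pd.Series, implausible_days: int = IMPLAUSIBLE_TTO_DAYS
) -> tuple[pd.Series, pd.Series]:
    """Vectorised :func:`compute_tto_days` -> (days float series, reason series)."""
    s = start.fillna("").astype(str).str.strip()
    e = event.fillna("").astype(str).str.strip()
    missing = (s == "") | (e == "")
    full8 = (s.str.len() == 8) & s.str.isdigit() & (e.str.len() == 8) & e.str.isdigit()
    sd = pd.to_datetime(s.where(full8), format="%Y%m%d", errors="coerce")
    ed = pd.to_datetime(e.where(full8), format="%Y%m%d", errors="coerce")
    parseable = sd.notna() & ed.notna()
    incomplete = ~missing & ~parseable
    days = (ed - sd).dt.days
    inconsistent = parseable & (days <= 0)
    implausible = parseable & (days > implausible_days)
    ok = parseable & ~inconsistent & ~implausible

    reason = pd.Series("ok", index=start.index)
    reason[missing] = "missing"
    reason[incomplete] = "incomplete"
    reason[inconsistent] = "inconsistent"
    reason[implausible] = "implausible"
    out_days = days.where(ok).astype(float)
    return out_days, reason


# ---------------------------------------------------------------------------
# full dataset assembly
# ---------------------------------------------------------------------------

def prepare_dataset(
    bundle,
    name_map: Optional[DrugNameMap] = None,
    *,
    age_lower: float = 0.0,
    age_upper: float = 18.0,
    implausible_days: int = IMPLAUSIBLE_TTO_DAYS,
) -> tuple[pd.DataFrame, dict]:
    """Build the analysis dataset from a :class:`~faersig.faers_io.QuarterBundle`.

    Returns one row per deduplicated pediatric report with columns:
    primaryid, caseid, fda_dt, age_years, sex, country, occupation,
    outcomes, ps_verbatim, ps_entity, ps_class, ps_mapped, is_case_broad,
    is_case_narrow, tto_days, tto_reason — plus a QC dict mirroring the
    flowchart counts (raw, duplicates removed, pediatric retained,
    PS-assigned, cases).
    """
    if name_map is None:
        name_map = DrugNameMap.packaged()
    demo = bundle.table("DEMO")
    qc: dict = {"raw_reports": len(demo)}

    kept, dd = deduplicate(demo)
    qc.update({k: v for k, v in dd.items() if k != "input_rows"})

    age_vals = kept["age"] if "age" in kept.columns else pd.Series("", index=kept.index)
    age_cods = kept["age_cod"] if "age_cod" in kept.columns else pd.Series("", index=kept.index)
    kept = kept.assign(age_years=standardize_age_series(age_vals, age_cods))
    ped, pf = filter_pediatric(kept, lower=age_lower, upper=age_upper)
    qc["age_missing"] = pf["age_missing"]
    qc["age_out_of_range"] = pf["age_out_of_range"]
    qc["pediatric_retained"] = pf["retained"]

    pids = pd.Index(ped["primaryid"])

    # reactions -> case flags
    reac = bundle.table("REAC")
    reac = reac[reac["primaryid"].isin(pids)]
    code_col = "pt_cod" if "pt_cod" in reac.columns else "pt"
    codes = reac[code_col].astype(str).str.strip()
    broad, narrow = PtQuerySet.broad(), PtQuerySet.narrow()
    case_broad_ids = set(reac.loc[codes.isin(broad.pt_codes), "primaryid"])
    case_narrow_ids = set(reac.loc[codes.isin(narrow.pt_codes), "primaryid"])
    ped = ped.assign(
        is_case_broad=ped["primaryid"].isin(case_broad_ids),
        is_case_narrow=ped["primaryid"].isin(case_narrow_ids),
    )

    # primary-suspect drug
    drug = bundle.table("DRUG")
    drug = drug[drug["primaryid"].isin(pids)]
    ps = assign_primary_suspect_frame(drug)
    verb = ps.set_index("primaryid")["drugname"]
    ped = ped.assign(ps_verbatim=ped["primaryid"].map(verb))
    unique_names = ped["ps_verbatim"].dropna().unique()
    lookup = {v: name_map.lookup(v) for v in unique_names}
    ped = ped.assign(
        ps_entity=ped["ps_verbatim"].map(lambda v: lookup[v].entity if v in lookup else np.nan),
        ps_class=ped["ps_verbatim"].map(lambda v: lookup[v].drug_class if v in lookup else np.nan),
        ps_mapped=ped["ps_verbatim"].map(lambda v: lookup[v].mapped if v in lookup else False),
    )
    ps_seq = ps.set_index("primaryid")["drug_seq"]
    qc["ps_assigned"] = int(ped["ps_entity"].notna().sum())
    qc["unmapped_ps_names"] = int(
        sum(1 for v in unique_names if not lookup[v].mapped)
    )

    # therapy start for the PS drug, event date from DEMO
    ther = bundle.table("THER")
    ther = ther[ther["primaryid"].isin(pids)].copy()
    seq_map = ps_seq.astype(str).str.strip()
    ther_seq = ther["dsg_drug_seq"].astype(str).str.strip()
    ther_ps = ther[ther_seq.eq(ther["primaryid"].map(seq_map))]
    start = ther_ps.drop_duplicates("primaryid").set_index("primaryid")["start_dt"]
    event = (
        ped.set_index("primaryid")["event_dt"]
        if "event_dt" in ped.columns
        else pd.Series("", index=ped["primaryid"])
    )
    start_al = ped["primaryid"].map(start)
    tto_days, tto_reason = compute_tto_series(
        start_al, pd.Series(event.values, index=ped.index), implausible_days=implausible_days
    )
    ped = ped.assign(tto_days=tto_days.values, tto_reason=tto_reason.values)

    # outcomes (set of codes per report, serialised comma-joined)
    outc = bundle.table("OUTC")
    outc = outc[outc["primaryid"].isin(pids)]
    if len(outc):
        joined = outc.groupby("primaryid")["outc_cod"].apply(
            lambda s: ",".join(sorted(set(s)))
        )
        ped = ped.assign(outcomes=ped["primaryid"].map(joined).fillna(""))
    else:
        ped = ped.assign(outcomes="")

    qc["cases_broad"] = int(ped["is_case_broad"].sum())
    qc["cases_narrow"] = int(ped["is_case_narrow"].sum())
    qc["tto_categories_cases"] = (
        ped.loc[ped["is_case_broad"], "tto_reason"].value_counts().to_dict()
    )

    keep_cols = [
        c
        for c in (
            "primaryid", "caseid", "fda_dt", "age_years", "sex",
            "occp_cod", "reporter_country", "event_dt", "outcomes",
            "ps_verbatim", "ps_entity", "ps_class", "ps_mapped",
            "is_case_broad", "is_case_narrow", "tto_days", "tto_reason",
        )
        if c in ped.columns
    ]
    return ped[keep_cols].reset_index(drop=True), qc
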