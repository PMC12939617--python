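"""Synthetic FAERS-like quarter generator with known ground truth.

Emits DEMO/DRUG/REAC/THER/OUTC/INDI tables in the public quarterly-file
dialect, together with a :class:`GroundTruth` record of the latent state of
every report, so that each pipeline stage — deduplication, age
standardisation, Primary-Suspect selection, case definition, contingency
counting, time-to-onset categorisation — can be checked against an exact
brute-force recount rather than against itself.

What the generator emulates
---------------------------
* report-level demographics with mixed age units (YR/MON/WK/DY/DEC) and
  configurable missingness;
* CASEID-versioned duplicates: extra versions carry an *earlier* FDA_DT
  (exercising the latest-date rule) or, with configurable probability, the
  same FDA_DT and a smaller PRIMARYID (exercising the tie rule) — the base
  version is always the one the deduplication rule should keep;
* per-report drug lists with role codes and DRUG_SEQ ordering, including
  occasional second PS rows with a higher sequence number;
* MedDRA-PT reaction lists including the six cataract PTs;
* therapy start / event dates generated from a Weibull time-to-onset model
  with injected missing / incomplete / inconsistent / implausible
  pathologies (valid onsets are clipped to [1, implausible bound] so the
  injected categorisation is exact);
* planted drug–event associations: a drug's cataract probability is its
  rate ratio rho times the background probability, acting only through the
  Primary-Suspect drug.

Determinism: identical (config, seed) yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle, RawTable, assemble_quarter, write_bundle
from .case_definition import CATARACT_PTS_BROAD

NARROW_PT = "10007739"


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the synthetic world."""

    name: str
    prob: float
    drug_class: str = "other"


@dataclass(frozen=True)
class EventSpec:
    """One background (non-cataract) reaction PT."""

    pt_code: str
    pt_name: str
    weight: float = 1.0


@dataclass(frozen=True)
class PlantedPair:
    """A planted drug–cataract association at reporting-rate ratio rho.

    ``pt_codes`` optionally restricts which cataract PTs planted cases
    carry (e.g. only the narrow PT).
    """

    drug: str
    rate_ratio: float
    pt_codes: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class AgeModel:
    pediatric_fraction: float = 0.85
    missing_prob: float = 0.05
    unit_probs: tuple[tuple[str, float], ...] = (
        ("YR", 0.55), ("MON", 0.25), ("WK", 0.05), ("DY", 0.10), ("DEC", 0.05),
    )
    ped_lo: float = 0.25
    ped_hi: float = 17.75
    adult_lo: float = 18.5
    adult_hi: float = 85.0


@dataclass(frozen=True)
class DateModel:
    start_lo: str = "20050101"
    start_hi: str = "20240101"
    weibull_shape: float = 0.72
    weibull_scale: float = 300.0
    p_missing: float = 0.10
    p_incomplete: float = 0.03
    p_inconsistent: float = 0.02
    p_implausible: float = 0.0
    implausible_days: int = 6574

    @property
    def p_ok(self) -> float:
        return 1.0 - (
            self.p_missing + self.p_incomplete + self.p_inconsistent + self.p_implausible
        )


_DEFAULT_EVENTS = (
    EventSpec("10019211", "Headache", 1.5),
    EventSpec("10028813", "Nausea", 1.2),
    EventSpec("10047700", "Vomiting", 1.0),
    EventSpec("10037660", "Pyrexia", 1.0),
    EventSpec("10016256", "Fatigue", 0.8),
    EventSpec("10012735", "Diarrhoea", 0.8),
    EventSpec("10037844", "Rash", 0.7),
    EventSpec("10013573", "Dizziness", 0.6),
    EventSpec("10037087", "Pruritus", 0.5),
    EventSpec("10046735", "Urticaria", 0.4),
)

#: relative frequency of each cataract PT among generated cases
_DEFAULT_CATARACT_WEIGHTS = (
    ("10007739", 0.55),
    ("10024214", 0.15),
    ("10007748", 0.10),
    ("10007759", 0.10),
    ("10044135", 0.05),
    ("10069649", 0.05),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic FAERS world."""

    n_reports: int
    seed: int = 0
    drug_catalogue: tuple[DrugSpec, ...] = (
        DrugSpec("drug a", 0.30), DrugSpec("drug b", 0.30),
        DrugSpec("drug c", 0.20), DrugSpec("drug d", 0.20),
    )
    event_catalogue: tuple[EventSpec, ...] = _DEFAULT_EVENTS
    cataract_background_prob: float = 0.001
    cataract_pt_weights: tuple[tuple[str, float], ...] = _DEFAULT_CATARACT_WEIGHTS
    planted_pairs: tuple[PlantedPair, ...] = ()
    duplicate_fraction: float = 0.2
    dup_tie_prob: float = 0.3
    age: AgeModel = AgeModel()
    dates: DateModel = DateModel()
    sex_probs: tuple[tuple[str, float], ...] = (("M", 0.48), ("F", 0.48), ("UNK", 0.04))
    occupation_probs: tuple[tuple[str, float], ...] = (
        ("MD", 0.35), ("PH", 0.12), ("OT", 0.12), ("CN", 0.38), ("LW", 0.03),
    )
    country_probs: tuple[tuple[str, float], ...] = (
        ("US", 0.5), ("CA", 0.1), ("GB", 0.1), ("FR", 0.08), ("DE", 0.08),
        ("JP", 0.08), ("BR", 0.06),
    )
    outcome_probs: tuple[tuple[str, float], ...] = (
        ("DE", 0.01), ("LT", 0.01), ("HO", 0.10), ("DS", 0.02), ("OT", 0.30),
    )
    extra_ps_prob: float = 0.05
    quarter_label: str = "2018Q3"

    def validate(self) -> None:
        if self.n_reports < 0:
            raise GeneratorConfigError("n_reports must be >= 0")
        probs = [d.prob for d in self.drug_catalogue]
        if not probs or min(probs) < 0 or sum(probs) <= 0:
            raise GeneratorConfigError("drug catalogue needs non-negative probabilities")
        names = [d.name for d in self.drug_catalogue]
        if len(set(names)) != len(names):
            raise GeneratorConfigError("duplicate drug names in catalogue")
        known = set(names)
        for pair in self.planted_pairs:
            if pair.rate_ratio < 0:
                raise GeneratorConfigError("rate ratio must be >= 0")
            if pair.drug not in known:
                raise GeneratorConfigError(f"planted drug {pair.drug!r} not in catalogue")
            if pair.rate_ratio * self.cataract_background_prob > 1.0:
                raise GeneratorConfigError(
                    f"infeasible: rho * background > 1 for {pair.drug!r}"
                )
            if pair.pt_codes is not None:
                bad = set(pair.pt_codes) - set(CATARACT_PTS_BROAD)
                if bad:
                    raise GeneratorConfigError(f"unknown cataract PTs {bad}")
        for p in (self.duplicate_fraction, self.dup_tie_prob, self.extra_ps_prob,
                  self.cataract_background_prob, self.age.pediatric_fraction,
                  self.age.missing_prob):
            if not (0.0 <= p <= 1.0):
                raise GeneratorConfigError(f"probability {p} outside [0, 1]")
        if self.dates.p_ok < 0:
            raise GeneratorConfigError("date pathology probabilities sum above 1")

    def rho_of(self) -> dict[str, float]:
        rho = {d.name: 1.0 for d in self.drug_catalogue}
        for pair in self.planted_pairs:
            rho[pair.drug] = pair.rate_ratio
        return rho

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=list))
        return path


@dataclass
class GroundTruth:
    """Latent per-report state plus exact expected contingency counts."""

    frame: pd.DataFrame  # one row per caseid (the version dedup must keep)
    config: GeneratorConfig

    @property
    def n_base_reports(self) -> int:
        return len(self.frame)

    @property
    def background(self) -> pd.DataFrame:
        """Reports an ideal pipeline retains: deduplicated + pediatric."""
        f = self.frame
        return f[f["in_background"]]

    def expected_contingency(self, drug: str, query: str = "broad"):
        """Exact recount of the 2×2 table for one drug (oracle)."""
        from .disproportionality import ContingencyTable

        if drug not in {d.name for d in self.config.drug_catalogue}:
            raise ValueError(f"unknown drug {drug!r}")
        bg = self.background
        case = bg["is_case_narrow"] if query == "narrow" else bg["is_case_broad"]
        case = case.to_numpy(dtype=bool)
        exposed = (bg["ps_entity"] == drug).to_numpy(dtype=bool)
        return ContingencyTable(
            int((exposed & case).sum()),
            int((exposed & ~case).sum()),
            int((~exposed & case).sum()),
            int((~exposed & ~case).sum()),
        )

    def rejection_counts(self, cases_only: bool = False) -> dict[str, int]:
        bg = self.background
        if cases_only:
            bg = bg[bg["is_case_broad"]]
        out = {cat: int((bg["tto_reason"] == cat).sum())
               for cat in ("ok", "missing", "incomplete", "inconsistent", "implausible")}
        return out


@dataclass
class SyntheticWorld:
    bundle: QuarterBundle
    truth: GroundTruth
    config: GeneratorConfig

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        write_bundle(self.bundle, directory)
        self.truth.frame.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
        self.config.to_json(directory / "generator_config.json")
        return directory


def _choice(rng, pairs: Sequence[tuple[str, float]], size: int) -> np.ndarray:
    labels = np.array([p[0] for p in pairs], dtype=object)
    w = np.array([p[1] for p in pairs], dtype=float)
    return rng.choice(labels, size=size, p=w / w.sum())


def _fmt_age(values: np.ndarray) -> np.ndarray:
    out = np.empty(len(values), dtype=object)
    for i, v in enumerate(values):
        s = f"{v:.4f}".rstrip("0").rstrip(".")
        out[i] = s if s else "0"
    return out


_UNIT_TO_YEARS = {"YR": 1.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.0,
                  "DY": 1.0 / 365.0, "DEC": 10.0}


def generate(config: GeneratorConfig) -> SyntheticWorld:
    """Generate one synthetic quarter bundle plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    caseid_num = np.arange(n, dtype=np.int64) + 10_000_000
    caseid = caseid_num.astype(str)
    base_pid_num = caseid_num * 10 + 5  # versions 1..4 reserved for duplicates
    primaryid = base_pid_num.astype(str)

    # --- drugs -------------------------------------------------------------
    names = np.array([d.name for d in config.drug_catalogue], dtype=object)
    classes = {d.name: d.drug_class for d in config.drug_catalogue}
    probs = np.array([d.prob for d in config.drug_catalogue], dtype=float)
    probs = probs / probs.sum()
    ps_idx = rng.choice(len(names), size=n, p=probs)
    ps_drug = names[ps_idx]

    rho_map = config.rho_of()
    rho = np.array([rho_map[nm] for nm in names], dtype=float)[ps_idx]

    # --- case status and cataract PT --------------------------------------
    p_case = config.cataract_background_prob * rho
    is_case = rng.random(n) < p_case
    case_pt = _choice(rng, config.cataract_pt_weights, n)
    for pair in config.planted_pairs:
        if pair.pt_codes is not None:
            mask = is_case & (ps_drug == pair.drug)
            k = int(mask.sum())
            if k:
                weights = [(c, w) for c, w in config.cataract_pt_weights
                           if c in set(pair.pt_codes)]
                if not weights:
                    weights = [(c, 1.0) for c in pair.pt_codes]
                case_pt[mask] = _choice(rng, weights, k)

    # --- ages --------------------------------------------------------------
    am = config.age
    is_ped = rng.random(n) < am.pediatric_fraction
    latent_age = np.where(
        is_ped,
        rng.uniform(am.ped_lo, am.ped_hi, n),
        rng.uniform(am.adult_lo, am.adult_hi, n),
    )
    age_missing = rng.random(n) < am.missing_prob
    unit = _choice(rng, am.unit_probs, n)
    unit_factor = np.array([_UNIT_TO_YEARS[u] for u in unit], dtype=float)
    emitted_age_value = latent_age / unit_factor
    age_str = _fmt_age(emitted_age_value)
    age_str[age_missing] = ""
    age_cod = unit.copy()
    age_cod[age_missing] = ""
    # truth: parse the emitted string exactly as any reader would
    parsed = np.array(
        [float(s) * f if s != "" else np.nan for s, f in zip(age_str, unit_factor)],
        dtype=float,
    )
    truth_age = parsed
    in_background = ~np.isnan(truth_age) & (truth_age > 0.0) & (truth_age < 18.0)

    # --- demographics ------------------------------------------------------
    sex = _choice(rng, config.sex_probs, n)
    occp = _choice(rng, config.occupation_probs, n)
    country = _choice(rng, config.country_probs, n)

    # --- dates -------------------------------------------------------------
    dm = config.dates
    d0 = pd.Timestamp(dm.start_lo)
    span = max((pd.Timestamp(dm.start_hi) - d0).days, 1)
    start = d0 + pd.to_timedelta(rng.integers(0, span, size=n), unit="D")
    tto_raw = dm.weibull_scale * rng.weibull(dm.weibull_shape, size=n)
    tto_days = np.clip(np.ceil(tto_raw), 1, dm.implausible_days).astype(np.int64)

    cat_probs = np.array([dm.p_ok, dm.p_missing, dm.p_incomplete,
                          dm.p_inconsistent, dm.p_implausible])
    cats = np.array(["ok", "missing", "incomplete", "inconsistent", "implausible"],
                    dtype=object)
    tto_cat = rng.choice(cats, size=n, p=cat_probs / cat_probs.sum())

    back_days = rng.integers(0, 60, size=n)          # for inconsistent rows
    over_days = rng.integers(1, 1000, size=n)        # for implausible rows
    offset = tto_days.copy()
    offset[tto_cat == "inconsistent"] = -back_days[tto_cat == "inconsistent"]
    offset[tto_cat == "implausible"] = (
        dm.implausible_days + over_days[tto_cat == "implausible"]
    )
    event = start + pd.to_timedelta(offset, unit="D")

    start_str = np.array(start.strftime("%Y%m%d"), dtype=object)
    event_str = np.array(event.strftime("%Y%m%d"), dtype=object)
    u = rng.random(n)
    m = tto_cat == "missing"
    event_str[m & (u < 0.5)] = ""
    start_str[m & (u >= 0.5) & (u < 0.8)] = ""
    both = m & (u >= 0.8)
    start_str[both] = ""
    event_str[both] = ""
    inc = tto_cat == "incomplete"
    trunc_start = inc & (u < 0.5)
    trunc_event = inc & (u >= 0.5)
    start_str[trunc_start] = [s[:6] for s in start_str[trunc_start]]
    event_str[trunc_event] = [s[:6] for s in event_str[trunc_event]]

    fda = start + pd.to_timedelta(
        np.abs(offset) + rng.integers(10, 400, size=n), unit="D"
    )
    fda_str = np.array(fda.strftime("%Y%m%d"), dtype=object)

    truth_days = np.where(tto_cat == "ok", tto_days, np.nan).astype(float)

    # --- DEMO (base versions) ---------------------------------------------
    demo = pd.DataFrame(
        {
            "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_str,
            "event_dt": event_str, "age": age_str, "age_cod": age_cod,
            "sex": sex, "occp_cod": occp, "reporter_country": country,
        }
    )

    # --- DRUG / THER -------------------------------------------------------
    routes = _choice(
        rng,
        (("ORAL", 0.45), ("INTRAVENOUS", 0.2), ("SUBCUTANEOUS", 0.1),
         ("OPHTHALMIC", 0.1), ("UNKNOWN", 0.15)),
        n,
    )
    drug_frames = [
        pd.DataFrame(
            {
                "primaryid": primaryid, "caseid": caseid, "drug_seq": "1",
                "role_cod": "PS",
                "drugname": np.array([s.upper() for s in ps_drug], dtype=object),
                "route": routes,
            }
        )
    ]
    extra_ps = rng.random(n) < config.extra_ps_prob
    extra_drug = names[rng.choice(len(names), size=n, p=probs)]
    if extra_ps.any():
        drug_frames.append(
            pd.DataFrame(
                {
                    "primaryid": primaryid[extra_ps], "caseid": caseid[extra_ps],
                    "drug_seq": "2", "role_cod": "PS",
                    "drugname": np.array(
                        [s.upper() for s in extra_drug[extra_ps]], dtype=object
                    ),
                    "route": routes[extra_ps],
                }
            )
        )
    n_con = rng.integers(0, 3, size=n)
    con_pid = np.repeat(primaryid, n_con)
    con_case = np.repeat(caseid, n_con)
    con_seq = (np.concatenate([np.arange(k) for k in n_con]) + 3).astype(str) if n_con.sum() else np.array([], dtype=object)
    con_drug = names[rng.choice(len(names), size=int(n_con.sum()), p=probs)]
    if len(con_pid):
        drug_frames.append(
            pd.DataFrame(
                {
                    "primaryid": con_pid, "caseid": con_case, "drug_seq": con_seq,
                    "role_cod": "C",
                    "drugname": np.array([s.upper() for s in con_drug], dtype=object),
                    "route": "UNKNOWN",
                }
            )
        )
    drug_tbl = pd.concat(drug_frames, ignore_index=True)

    ther_tbl = pd.DataFrame(
        {
            "primaryid": primaryid, "caseid": caseid, "dsg_drug_seq": "1",
            "start_dt": start_str, "end_dt": "",
        }
    )

    # --- REAC --------------------------------------------------------------
    pt_names_map = dict(CATARACT_PTS_BROAD)
    pt_names_map.update({e.pt_code: e.pt_name for e in config.event_catalogue})
    n_extra = rng.integers(1, 4, size=n)
    bg_codes = np.array([e.pt_code for e in config.event_catalogue], dtype=object)
    bg_w = np.array([e.weight for e in config.event_catalogue], dtype=float)
    extra_codes = rng.choice(bg_codes, size=int(n_extra.sum()), p=bg_w / bg_w.sum())
    reac_pid = np.concatenate([primaryid[is_case], np.repeat(primaryid, n_extra)])
    reac_case = np.concatenate([caseid[is_case], np.repeat(caseid, n_extra)])
    reac_cod = np.concatenate([case_pt[is_case], extra_codes])
    reac_tbl = pd.DataFrame(
        {
            "primaryid": reac_pid, "caseid": reac_case,
            "pt": np.array([pt_names_map[c] for c in reac_cod], dtype=object),
            "pt_cod": reac_cod,
        }
    )

    # --- OUTC / INDI -------------------------------------------------------
    outc_parts = []
    for code, p in config.outcome_probs:
        mask = rng.random(n) < p
        if mask.any():
            outc_parts.append(
                pd.DataFrame(
                    {"primaryid": primaryid[mask], "caseid": caseid[mask],
                     "outc_cod": code}
                )
            )
    outc_tbl = (
        pd.concat(outc_parts, ignore_index=True)
        if outc_parts
        else pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"], dtype=str)
    )
    indications = (
        "Product used for unknown indication", "Juvenile idiopathic arthritis",
        "Cystic fibrosis", "Retinoblastoma", "Asthma", "Nephrotic syndrome",
    )
    indi_tbl = pd.DataFrame(
        {
            "primaryid": primaryid, "caseid": caseid, "indi_drug_seq": "1",
            "indi_pt": _choice(rng, tuple((i, 1.0) for i in indications), n),
        }
    )

    # --- duplicate versions ------------------------------------------------
    dup = rng.random(n) < config.duplicate_fraction
    n_versions = np.ones(n, dtype=np.int64)
    extra_counts = 1 + (rng.random(n) < 0.3).astype(np.int64)  # 1 or 2 extras
    n_versions[dup] += extra_counts[dup]
    tie = rng.random(n) < config.dup_tie_prob
    back_fda = rng.integers(1, 400, size=n)

    dup_tables: dict[str, list[pd.DataFrame]] = {k: [] for k in
                                                 ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI")}
    if dup.any():
        content = {
            "DRUG": drug_tbl, "REAC": reac_tbl, "THER": ther_tbl,
            "OUTC": outc_tbl, "INDI": indi_tbl,
        }
        max_extra = int(extra_counts[dup].max())
        for v in range(1, max_extra + 1):
            sel = dup & (extra_counts >= v)
            old_pid = primaryid[sel]
            new_pid_num = caseid_num[sel] * 10 + (5 - v)  # smaller than base pid
            new_pid = new_pid_num.astype(str)
            # earlier FDA_DT, except ties (same FDA_DT, smaller PRIMARYID)
            dup_fda = np.where(
                tie[sel],
                fda_str[sel],
                np.array(
                    (fda[sel] - pd.to_timedelta(back_fda[sel] * v, unit="D")
                     ).strftime("%Y%m%d"),
                    dtype=object,
                ),
            )
            d = demo[sel].copy()
            d["primaryid"] = new_pid
            d["fda_dt"] = dup_fda
            dup_tables["DEMO"].append(d)
            pid_map = dict(zip(old_pid, new_pid))
            for kind, tbl in content.items():
                sub = tbl[tbl["primaryid"].isin(pid_map)].copy()
                sub["primaryid"] = sub["primaryid"].map(pid_map)
                dup_tables[kind].append(sub)

    def _with_dups(kind: str, base: pd.DataFrame) -> pd.DataFrame:
        parts = [base] + dup_tables[kind]
        return pd.concat(parts, ignore_index=True).astype(str) if len(parts) > 1 else base.astype(str)

    tables = [
        RawTable("DEMO", _with_dups("DEMO", demo), quarter_label=config.quarter_label),
        RawTable("DRUG", _with_dups("DRUG", drug_tbl), quarter_label=config.quarter_label),
        RawTable("REAC", _with_dups("REAC", reac_tbl), quarter_label=config.quarter_label),
        RawTable("THER", _with_dups("THER", ther_tbl), quarter_label=config.quarter_label),
        RawTable("OUTC", _with_dups("OUTC", outc_tbl), quarter_label=config.quarter_label),
        RawTable("INDI", _with_dups("INDI", indi_tbl), quarter_label=config.quarter_label),
    ]
    bundle = assemble_quarter(tables)

    truth_frame = pd.DataFrame(
        {
            "caseid": caseid,
            "kept_primaryid": primaryid,
            "n_versions": n_versions,
            "age_years": truth_age,
            "is_pediatric": in_background,
            "in_background": in_background,
            "ps_entity": ps_drug,
            "ps_class": np.array([classes[nm] for nm in ps_drug], dtype=object),
            "is_case_broad": is_case,
            "case_pt": np.where(is_case, case_pt, ""),
            "is_case_narrow": is_case & (case_pt == NARROW_PT),
            "tto_reason": tto_cat,
            "tto_days": truth_days,
            "sex": sex,
        }
    )
    truth = GroundTruth(truth_frame, config)
    return SyntheticWorld(bundle=bundle, truth=truth, config=config)


def expected_contingency(truth: GroundTruth, drug: str, query: str = "broad"):
    """Module-level oracle wrapper (see :meth:`GroundTruth.expected_contingency`)."""
    return truth.expected_contingency(drug, query=query)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: (name, exposure probability, class, planted rate ratio) for the preset
_PRESET_SIGNAL_DRUGS = (
    ("difluprednate", 0.0002, "glucocorticoid", 500.0),
    ("prednisolone acetate", 0.002, "glucocorticoid", 60.0),
    ("ranibizumab", 0.002, "monoclonal antibody", 45.0),
    ("ivacaftor", 0.004, "cftr modulator", 30.0),
    ("fluticasone furoate", 0.004, "glucocorticoid", 25.0),
    ("topotecan", 0.004, "antineoplastic", 16.0),
    ("elexacaftor/ivacaftor/tezacaftor", 0.006, "cftr modulator", 15.0),
    ("melphalan", 0.004, "antineoplastic", 14.0),
    ("ivacaftor/lumacaftor", 0.006, "cftr modulator", 13.0),
    ("triamcinolone acetonide", 0.010, "glucocorticoid", 10.0),
    ("prednisolone", 0.020, "glucocorticoid", 9.0),
    ("prednisone", 0.020, "glucocorticoid", 8.0),
    ("adalimumab", 0.030, "monoclonal antibody", 8.0),
    ("mycophenolate mofetil", 0.010, "immunosuppressant", 8.0),
    ("methotrexate", 0.025, "immunosuppressant", 7.0),
    ("cisplatin", 0.006, "antineoplastic", 7.0),
    ("dexamethasone", 0.015, "glucocorticoid", 6.0),
    ("methylprednisolone", 0.012, "glucocorticoid", 6.0),
    ("fluticasone propionate", 0.012, "glucocorticoid", 6.0),
    ("infliximab", 0.012, "monoclonal antibody", 6.0),
    ("filgrastim", 0.010, "colony-stimulating factor", 6.0),
    ("hydrocortisone", 0.012, "glucocorticoid", 5.0),
    ("budesonide", 0.012, "glucocorticoid", 5.0),
    ("topiramate", 0.012, "antiepileptic", 5.0),
)


def paper_like_config(n_reports: int = 50_000, seed: int = 0) -> GeneratorConfig:
    """A pediatric-only world with the 24 preset signal drugs planted.

    Exposure probabilities and rate ratios are fixed demo conditions:
    ophthalmic corticosteroids carry rare exposure but extreme rate ratios,
    systemic drugs common exposure and moderate ratios, and thirty null
    drugs absorb the remaining exposure mass.  Time to onset follows
    Weibull(shape 0.72, scale 300 days) with 70% missing, 10% incomplete
    and 2% inconsistent dates.
    """
    signal = [DrugSpec(nm, p, cls) for nm, p, cls, _ in _PRESET_SIGNAL_DRUGS]
    used = sum(p for _, p, _, _ in _PRESET_SIGNAL_DRUGS)
    n_null = 30
    null = [DrugSpec(f"background drug {i:02d}", (1.0 - used) / n_null)
            for i in range(1, n_null + 1)]
    pairs = tuple(
        PlantedPair(nm, rho) for nm, _, _, rho in _PRESET_SIGNAL_DRUGS
    )
    return GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalogue=tuple(signal + null),
        planted_pairs=pairs,
        cataract_background_prob=0.001,
        duplicate_fraction=0.2,
        age=AgeModel(pediatric_fraction=1.0, missing_prob=0.02),
        dates=DateModel(p_missing=0.70, p_incomplete=0.10, p_inconsistent=0.02),
    )


def null_config(
    n_reports: int = 5_000,
    seed: int = 0,
    n_drugs: int = 1,
    exposure_prob: float = 0.1,
    background_prob: float = 0.02,
) -> GeneratorConfig:
    """A world with no planted associations (every rate ratio is 1)."""
    share = exposure_prob
    rest = max(1.0 - n_drugs * share, 0.0)
    drugs = [DrugSpec(f"null drug {i:03d}", share) for i in range(n_drugs)]
    if rest > 0:
        drugs.append(DrugSpec("background drug", rest))
    return GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalogue=tuple(drugs),
        cataract_background_prob=background_prob,
        duplicate_fraction=0.0,
        age=AgeModel(pediatric_fraction=1.0, missing_prob=0.0),
        dates=DateModel(),
    )
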