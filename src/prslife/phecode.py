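"""Phecode case/control algorithm over raw ICD-9/ICD-10 billing events.

Billing events are reduced to per-phecode case/control/excluded partitions:

1. exact same-day duplicates (participant, date, vocabulary, code) collapse
   to one event, and events in vocabularies other than ICD9/ICD10 are dropped;
2. events join to phecodes through a mapping table (exact string match, no
   hierarchy rollup);
3. for each target phecode, a participant is a **case** with >= 2 mapped
   instances, **excluded** with exactly 1 instance (rule-out diagnoses) or —
   if not already a case — with any instance inside the phecode's exclusion
   ranges (related diseases that would contaminate the control pool), and a
   **control** otherwise.

Cases keep their case status even when they also carry exclusion-range codes;
exclusion ranges only clean the control pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EVENT_COLUMNS = ("participant_id", "date", "vocabulary", "code")
VALID_VOCABULARIES = ("ICD9", "ICD10")


class PhecodeError(ValueError):
    pass


def _parse_ranges(spec: str) -> list[tuple[float, float]]:
    """Parse exclusion ranges like '278-279.99' or '240-249.99;255-255.99'."""
    if not isinstance(spec, str) or not spec.strip():
        return []
    out = []
    for part in spec.split(";"):
        lo, hi = part.strip().split("-")
        lo, hi = float(lo), float(hi)
        if lo > hi:
            raise PhecodeError(f"ill-ordered exclusion range {part!r}")
        out.append((lo, hi))
    return out


@dataclass(frozen=True)
class PhecodeMap:
    """ICD→phecode mapping plus per-phecode metadata and exclusion ranges."""

    icd_map: pd.DataFrame = field(repr=False)  # vocabulary, code, phecode
    defs: pd.DataFrame = field(repr=False)  # phecode, label, group, exclude_range

    def __post_init__(self) -> None:
        for col in ("vocabulary", "code", "phecode"):
            if col not in self.icd_map.columns:
                raise PhecodeError(f"icd map is missing column {col!r}")
        for col in ("phecode", "label", "group"):
            if col not in self.defs.columns:
                raise PhecodeError(f"phecode definitions are missing column {col!r}")

    @property
    def phecodes(self) -> list[str]:
        return self.defs["phecode"].tolist()

    def exclusion_ranges(self, phecode: str) -> list[tuple[float, float]]:
        row = self.defs.loc[self.defs["phecode"] == phecode]
        if row.empty:
            raise PhecodeError(f"phecode {phecode!r} not in map")
        spec = row.iloc[0].get("exclude_range", "")
        return _parse_ranges(spec if isinstance(spec, str) else "")

    def codes_for(self, phecode: str) -> pd.DataFrame:
        """Mapped (vocabulary, code) rows for one phecode."""
        sub = self.icd_map.loc[self.icd_map["phecode"] == phecode, ["vocabulary", "code"]]
        if sub.empty:
            raise PhecodeError(f"phecode {phecode!r} has no mapped ICD codes")
        return sub.reset_index(drop=True)

    def label(self, phecode: str) -> str:
        row = self.defs.loc[self.defs["phecode"] == phecode]
        return "" if row.empty else str(row.iloc[0]["label"])

    def group(self, phecode: str) -> str:
        row = self.defs.loc[self.defs["phecode"] == phecode]
        return "" if row.empty else str(row.iloc[0]["group"])


def load_phecode_map(map_path: str | Path, defs_path: str | Path) -> PhecodeMap:
    icd_map = pd.read_csv(map_path, dtype=str)
    defs = pd.read_csv(defs_path, dtype=str).fillna({"exclude_range": ""})
    for pc in defs["phecode"]:
        try:
            float(pc)
        except ValueError:
            raise PhecodeError(f"phecode {pc!r} is not numeric-dotted") from None
    return PhecodeMap(icd_map=icd_map, defs=defs)


def default_phecode_map() -> PhecodeMap:
    """The 40-phecode synthetic toy map shipped with the package.

    Phecode 278.1 (obesity) carries a realistic ICD-9/ICD-10 code list; the
    other 39 phecodes and their code assignments are synthetic.
    """
    data = resources.files("prslife.data")
    with resources.as_file(data / "phecode_map_synthetic.csv") as m, resources.as_file(
        data / "phecode_defs_synthetic.csv"
    ) as d:
        return load_phecode_map(m, d)


def dedupe_events(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact same-day duplicates; drop non-ICD-9/-10 vocabularies."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise PhecodeError(f"event table is missing column(s): {missing}")
    known = events["vocabulary"].isin(VALID_VOCABULARIES)
    n_dropped = int((~known).sum())
    if n_dropped:
        log.info("dropped %d event(s) with non-ICD-9/-10 vocabulary", n_dropped)
    return events.loc[known].drop_duplicates(subset=list(EVENT_COLUMNS)).reset_index(drop=True)


def map_events(events: pd.DataFrame, pmap: PhecodeMap) -> pd.DataFrame:
    """Join deduped events to phecodes; unmapped codes are counted, not fatal."""
    merged = events.merge(pmap.icd_map, on=["vocabulary", "code"], how="left")
    unmapped = merged["phecode"].isna()
    if unmapped.any():
        log.info("%d event(s) had no phecode mapping", int(unmapped.sum()))
    return (
        merged.loc[~unmapped, ["participant_id", "date", "phecode"]]
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class CaseControlSet:
    """Case/control/excluded partition of the cohort for one phecode."""

    phecode: str
    cases: pd.Index = field(repr=False)
    controls: pd.Index = field(repr=False)
    excluded: pd.DataFrame = field(repr=False)  # participant_id, reason

    def __post_init__(self) -> None:
        sets = [set(self.cases), set(self.controls), set(self.excluded["participant_id"])]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise PhecodeError(f"case/control/excluded sets overlap for phecode {self.phecode}")

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    def status(self) -> pd.Series:
        """0/1 outcome over cases+controls (excluded participants absent)."""
        s = pd.concat(
            [
                pd.Series(1, index=self.cases, dtype=int),
                pd.Series(0, index=self.controls, dtype=int),
            ]
        )
        s.index.name = "participant_id"
        return s.rename(self.phecode)


def build_case_control(
    instances: pd.DataFrame, pmap: PhecodeMap, phecode: str, cohort_ids
) -> CaseControlSet:
    """Partition the cohort into cases/controls/excluded for one phecode.

    ``instances`` is the deduped, mapped phecode-instance table.  Counting is
    over instances surviving same-day dedup of exact duplicates, so two
    different ICD codes mapping to the same phecode on the same day count as
    two instances.
    """
    if phecode not in set(pmap.defs["phecode"]):
        raise PhecodeError(f"phecode {phecode!r} absent from map")
    cohort = pd.Index(cohort_ids, name="participant_id")
    inst = instances[instances["participant_id"].isin(cohort)]

    counts = inst.loc[inst["phecode"] == phecode].groupby("participant_id").size()
    cases = pd.Index(counts.index[counts >= 2])
    one_code = pd.Index(counts.index[counts == 1])

    ranges = pmap.exclusion_ranges(phecode)
    if ranges:
        pc_num = pd.to_numeric(inst["phecode"], errors="coerce")
        in_range = np.zeros(len(inst), dtype=bool)
        for lo, hi in ranges:
            in_range |= ((pc_num >= lo) & (pc_num <= hi)).to_numpy()
        range_carriers = pd.Index(inst.loc[in_range, "participant_id"].unique())
    else:
        range_carriers = pd.Index([])

    # cases stay cases; one-code takes precedence as the recorded reason
    range_excluded = range_carriers.difference(cases).difference(one_code)
    excluded = pd.DataFrame(
        {
            "participant_id": list(one_code) + list(range_excluded),
            "reason": ["one_code"] * len(one_code) + ["exclusion_range"] * len(range_excluded),
        }
    )
    controls = cohort.difference(cases).difference(one_code).difference(range_excluded)
    return CaseControlSet(phecode=phecode, cases=cases, controls=controls, excluded=excluded)


def build_all_case_controls(
    instances: pd.DataFrame, pmap: PhecodeMap, cohort_ids, phecodes=None
) -> dict[str, CaseControlSet]:
    """Independent case/control sets for every (or the given) phecode(s)."""
    phecodes = list(phecodes) if phecodes is not None else pmap.phecodes
    return {pc: build_case_control(instances, pmap, pc, cohort_ids) for pc in phecodes}


def restrict_post_enrollment(
    events: pd.DataFrame, enrollment_dates: pd.Series, min_days: int = 365
) -> pd.DataFrame:
    """Keep only events dated >= enrollment + ``min_days`` (inclusive).

    Used for the sensitivity analysis restricting to diagnoses made one year
    or later after biobank enrollment.
    """
    enrollment = pd.Series(enrollment_dates)
    missing = pd.Index(events["participant_id"].unique()).difference(enrollment.index)
    if len(missing):
        raise PhecodeError(f"missing enrollment date for participant(s): {sorted(missing)[:10]}")
    enr = events["participant_id"].map(enrollment)
    cutoff = pd.to_datetime(enr) + pd.to_timedelta(min_days, unit="D")
    keep = pd.to_datetime(events["date"]) >= cutoff
    return events.loc[keep].reset_index(drop=True)
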