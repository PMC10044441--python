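"""Trait derivation, contemporary grouping, and record filtering.

This module turns raw field records (breeding-soundness exams on bulls,
rebreeding/pregnancy outcomes on females) into model-ready tables:

* derived traits — testicular volume from caliper width/length, testicular
  format class from the width:length ratio, calving-rest-interval classes,
  binary success/failure coding (1 = failure, 2 = success);
* contemporary groups (CG) — animals born on the same farm, year and season,
  of the same sex and management group; for traits where the weaning
  management group (GMAND) is fitted as its own uncorrelated random effect it
  is left out of the CG key;
* record filters — +-3.5 SD trimming within CG (continuous traits only),
  removal of CGs that are too small, phenotypically invariant, sired by fewer
  than two bulls, or that contain unknown-pedigree animals.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: contemporary-group key fields
CG_FIELDS = ("farm", "birth_year", "birth_season", "sex", "management_group")

SUCCESS, FAILURE = 2, 1


# ---------------------------------------------------------------------------
# trait derivations
# ---------------------------------------------------------------------------


def derive_testicular_volume(
    width_cm: float, length_cm: float, radius_rule: str = "half-width"
) -> float:
    """Testicular volume in dm^3 for the pair of testes: 2 * (r^2 * pi * L).

    ``radius_rule`` chooses how the caliper width maps to a radius:
    "half-width" (r = width/2, the geometric reading) or "quarter-width"
    (r = width/4, which lands in the range of published Nellore TV means).
    Inputs in cm; the cm^3 result is divided by 1000.
    """
    if width_cm < 0 or length_cm < 0:
        raise ValueError("testicular width/length must be non-negative")
    if radius_rule == "half-width":
        r = width_cm / 2.0
    elif radius_rule == "quarter-width":
        r = width_cm / 4.0
    else:
        raise ValueError(f"unknown radius_rule {radius_rule!r}")
    return 2.0 * (r * r) * math.pi * length_cm / 1000.0


#: testicular-format class edges on the width:length ratio; membership at an
#: edge goes to the lower class except the explicitly strict "> 0.875"
_TF_EDGES = (0.5, 0.625, 0.75, 0.875)
TF_CLASS_NAMES = {1: "long", 2: "long-moderate", 3: "long-oval",
                  4: "oval-spherical", 5: "spherical"}


def classify_testicular_format(mean_width: float, mean_length: float) -> int:
    """Testicular format class 1..5 from mean width / mean length."""
    if mean_length <= 0:
        raise ValueError("mean testicular length must be positive")
    ratio = mean_width / mean_length
    for cls, edge in enumerate(_TF_EDGES, start=1):
        if ratio <= edge:
            return cls
    return 5


#: calving-rest-interval class upper edges in days (closed integer bins);
#: day 151 and beyond is class 5
_CRI_EDGES = (60, 90, 120, 150)


def assign_cri_class(days: int) -> int:
    """Calving-rest-interval class 1..5: [0,60], [61,90], [91,120],
    [121,150], [151,inf)."""
    if days < 0:
        raise ValueError("calving rest interval must be non-negative")
    for cls, edge in enumerate(_CRI_EDGES, start=1):
        if days <= edge:
            return cls
    return 5


DEFAULT_OUTCOME_ALIASES = {
    "success": SUCCESS, "failure": FAILURE,
    "pregnant": SUCCESS, "open": FAILURE,
    "2": SUCCESS, "1": FAILURE, 2: SUCCESS, 1: FAILURE,
}


def code_binary_trait(raw_outcome, aliases=None) -> int:
    """Map a success/failure outcome to the 2/1 coding (2 = success)."""
    table = dict(DEFAULT_OUTCOME_ALIASES)
    if aliases:
        table.update(aliases)
    key = raw_outcome.strip().lower() if isinstance(raw_outcome, str) else raw_outcome
    try:
        return table[key]
    except KeyError:
        raise ValueError(f"unknown binary outcome label {raw_outcome!r}") from None


# ---------------------------------------------------------------------------
# model templates (one per trait of the study design)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One trait's model: fixed class effects, covariates (name, exponent),
    optional uncorrelated random group, plus the additive animal effect with
    (co)variance structured by H (always present)."""

    trait_name: str
    kind: str  # "linear" | "threshold"
    fixed_class_effects: tuple = ("CG",)
    covariates: tuple = ()  # ((column, exponent), ...)
    uncorrelated_random: str | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "threshold"):
            raise ValueError(f"trait kind must be linear/threshold, got {self.kind!r}")


def _male_linear(name, gmand=False):
    return ModelSpec(
        trait_name=name,
        kind="linear",
        fixed_class_effects=("CG",),
        covariates=(("idap", 1), ("idap", 2)),
        uncorrelated_random="gmand" if gmand else None,
    )


#: the study's model roster: male BSE traits fit CG + age + age^2 (+ GMAND for
#: scrotal circumference); rebreeding traits add the calving-rest class;
#: pregnancy-at-14-months adds calf birth date and GMAND; stayability is CG only.
STUDY_MODELS: dict[str, ModelSpec] = {
    **{
        t: _male_linear(t)
        for t in (
            "VOL", "VIG", "TURB", "MOT", "LTL", "RTL", "LTW", "RTW",
            "VESIC_L", "VESIC_W", "TV", "TF", "MID", "MAD", "TD",
            "SMN_ASPC", "BULL_FIT",
        )
    },
    "SC": _male_linear("SC", gmand=True),
    "REB": ModelSpec("REB", "threshold", ("CG", "CRI"), ()),
    "REBB": ModelSpec("REBB", "threshold", ("CG", "CRI"), ()),
    "REBA": ModelSpec("REBA", "threshold", ("CG", "CRI"), ()),
    "PP14": ModelSpec("PP14", "threshold", ("CG",), (("dtjn", 1),), "gmand"),
    "STAY": ModelSpec("STAY", "threshold", ("CG",), ()),
}


def study_model(trait_name: str) -> ModelSpec:
    try:
        return STUDY_MODELS[trait_name]
    except KeyError:
        raise KeyError(
            f"no packaged model template for trait {trait_name!r}; "
            f"known traits: {sorted(STUDY_MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# contemporary groups
# ---------------------------------------------------------------------------

DEFAULT_SEASON_MAP = {m: ("wet" if m in (10, 11, 12, 1, 2, 3) else "dry")
                      for m in range(1, 13)}


def season_from_month(month: int, season_map=None) -> str:
    """Birth season from birth month (configurable map; default wet Oct-Mar,
    dry Apr-Sep, the usual split for central-Brazil pastures)."""
    table = season_map or DEFAULT_SEASON_MAP
    return table[int(month)]


def build_contemporary_groups(
    records: pd.DataFrame, model: ModelSpec | None = None
) -> pd.DataFrame:
    """Attach a ``cg`` key column: farm|year|season|sex|management-group.

    When the model fits the weaning management group as its own uncorrelated
    random effect, the management group is excluded from the CG key.  Records
    missing any key field are dropped (logged).
    """
    fields = list(CG_FIELDS)
    if model is not None and model.uncorrelated_random is not None:
        fields.remove("management_group")
    missing = records[fields].isna().any(axis=1)
    if missing.any():
        logger.info("dropping %d records with missing CG fields", int(missing.sum()))
    out = records.loc[~missing].copy()
    out["cg"] = out[fields].astype(str).agg("|".join, axis=1)
    return out


# ---------------------------------------------------------------------------
# record filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    records_in: int
    dropped_sd_outlier: int = 0
    dropped_small_cg: int = 0
    dropped_novar_cg: int = 0
    dropped_sire_or_pedigree: int = 0
    records_out: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def filter_records(
    records: pd.DataFrame,
    kind: str = "linear",
    sd_limit: float = 3.5,
    min_cg_size: int = 5,
    min_sires: int = 2,
) -> tuple[pd.DataFrame, FilterReport]:
    """Single-pass record filters applied after CG assignment.

    1. drop records farther than ``sd_limit`` SDs from their CG mean
       (continuous traits only; never applied to binary traits);
    2. drop CGs with fewer than ``min_cg_size`` animals;
    3. drop CGs with no phenotypic variability (continuous: zero SD;
       binary: a single category);
    4. drop CGs with progeny of fewer than ``min_sires`` distinct sires or
       containing animals of unknown pedigree (no known sire).

    Columns required: ``cg``, ``value``; rule 4 uses ``sire_id`` (empty/NaN =
    unknown).  The pass is idempotent on its own output.
    """
    rep = FilterReport(records_in=len(records))
    df = records.copy()

    if kind == "linear":
        grp = df.groupby("cg")["value"]
        mean = grp.transform("mean")
        sd = grp.transform("std").fillna(0.0)
        keep = (df["value"] - mean).abs() <= sd_limit * sd + 1e-12
        rep.dropped_sd_outlier = int((~keep).sum())
        df = df.loc[keep]

    size = df.groupby("cg")["value"].transform("size")
    keep = size >= min_cg_size
    rep.dropped_small_cg = int((~keep).sum())
    df = df.loc[keep]

    if kind == "linear":
        var = df.groupby("cg")["value"].transform("std").fillna(0.0)
        keep = var > 0.0
    else:
        nuniq = df.groupby("cg")["value"].transform("nunique")
        keep = nuniq > 1
    rep.dropped_novar_cg = int((~keep).sum())
    df = df.loc[keep]

    if "sire_id" in df.columns:
        sire = df["sire_id"].astype("string")
        known = sire.notna() & (sire != "") & (sire != "0")
        nsires = df.assign(_s=sire.where(known)).groupby("cg")["_s"].transform(
            "nunique"
        )
        all_known = known.groupby(df["cg"]).transform("all")
        keep = (nsires >= min_sires) & all_known
        rep.dropped_sire_or_pedigree = int((~keep).sum())
        df = df.loc[keep]

    rep.records_out = len(df)
    logger.info(
        "record filters: %d -> %d (outliers %d, small CG %d, no-variance CG "
        "%d, sire/pedigree %d)",
        rep.records_in, rep.records_out, rep.dropped_sd_outlier,
        rep.dropped_small_cg, rep.dropped_novar_cg, rep.dropped_sire_or_pedigree,
    )
    return df.reset_index(drop=True), rep


def prepare_trait_table(
    records: pd.DataFrame,
    model: ModelSpec,
    sd_limit: float = 3.5,
    min_cg_size: int = 5,
    min_sires: int = 2,
) -> tuple[pd.DataFrame, FilterReport]:
    """CG assignment, CRI classing (if modeled), and record filtering for one
    trait, returning a model-ready table."""
    df = build_contemporary_groups(records, model)
    if "CRI" in model.fixed_class_effects:
        df = df.copy()
        df["cri_class"] = df["cri_days"].astype(int).map(assign_cri_class)
    return filter_records(
        df, kind=model.kind, sd_limit=sd_limit,
        min_cg_size=min_cg_size, min_sires=min_sires,
    )
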