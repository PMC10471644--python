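"""Domain types and delimited-table I/O.

The package revolves around three tables:

* a **taxon PUFA table** — per-taxon mean/SD mass fractions (µg/mg dry weight)
  of arachidonic (ARA), eicosapentaenoic (EPA) and docosahexaenoic (DHA) acid,
  plus the ordinal content class (1–5) per PUFA;
* a **lake survey table** — one row per littoral site visit with habitat codes,
  water-chemistry covariates and per-taxon abundance counts (individuals per
  standard kick-net sampling effort);
* a **community response table** — the derived per-site response variables
  (richness, weighted PUFA indices, counts/percentages of PUFA-rich taxa).

All files are plain UTF-8 CSV with ``.`` as the decimal separator.  Missing
standard deviations (taxa sampled in a single lake) are written as empty
fields and also accepted as the en-dash ``–`` on input; they are kept missing,
never imputed.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical lower-case PUFA keys used throughout the package.
PUFAS: tuple[str, str, str] = ("ara", "epa", "dha")

#: Fixed (non-taxon) columns of a wide-format survey table, in writing order.
SURVEY_FIXED_COLUMNS: tuple[str, ...] = (
    "lake_id",
    "site_id",
    "lake_type",
    "vegetation",
    "substrate",
    "latitude",
    "color",
    "ph",
    "tp",
    "tn",
)

_MISSING_TOKENS = {"", "–", "-", "nan", "NA", "NaN"}


class TableFormatError(ValueError):
    """Raised when a delimited table cannot be parsed into domain records."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class TaxonPufaProfile:
    """Per-taxon PUFA summary: mass fractions (µg/mg DW) and ordinal classes.

    ``n_lakes`` is the number of lakes in which the taxon was sampled.  Class 1
    marks "not detected" and therefore must coincide with a zero mean; missing
    SDs (``None``) arise for taxa sampled in a single lake.
    """

    taxon: str
    n_lakes: int
    mean_ara: float
    sd_ara: float | None
    class_ara: int
    mean_epa: float
    sd_epa: float | None
    class_epa: int
    mean_dha: float
    sd_dha: float | None
    class_dha: int

    def __post_init__(self) -> None:
        _check(bool(self.taxon), "taxon label must be non-empty")
        _check(self.n_lakes >= 1, f"{self.taxon}: n_lakes must be >= 1")
        for pufa in PUFAS:
            mean = self.mean_for(pufa)
            sd = self.sd_for(pufa)
            cls = self.class_for(pufa)
            _check(
                math.isfinite(mean) and mean >= 0.0,
                f"{self.taxon}: {pufa.upper()} mean must be finite and >= 0",
            )
            _check(
                sd is None or (math.isfinite(sd) and sd >= 0.0),
                f"{self.taxon}: {pufa.upper()} SD must be >= 0 or missing",
            )
            _check(cls in (1, 2, 3, 4, 5), f"{self.taxon}: class must be 1..5")
            _check(
                (cls == 1) == (mean == 0.0),
                f"{self.taxon}: class 1 if and only if {pufa.upper()} not detected",
            )

    def mean_for(self, pufa: str) -> float:
        return float(getattr(self, f"mean_{pufa}"))

    def sd_for(self, pufa: str) -> float | None:
        sd = getattr(self, f"sd_{pufa}")
        return None if sd is None else float(sd)

    def class_for(self, pufa: str) -> int:
        return int(getattr(self, f"class_{pufa}"))


@dataclass(frozen=True)
class LakeMeta:
    """Provenance record for a fatty-acid survey lake."""

    lake_id: str
    name: str
    area: float  # hectares
    color: float | None = None
    tn: float | None = None
    tp: float | None = None

    def __post_init__(self) -> None:
        _check(self.area > 0, f"{self.lake_id}: lake area must be positive")


@dataclass(frozen=True)
class SurveySample:
    """One littoral site visit: habitat codes, water chemistry, abundances.

    Continuous covariates must be strictly positive because the downstream
    ANCOVA enters them as natural logs.  ``abundances`` maps taxon label to a
    count of individuals per standard sampling effort.
    """

    lake_id: str
    site_id: str
    lake_type: str
    vegetation: str
    substrate: str
    latitude: float  # decimal degrees, WGS84
    color: float  # mg Pt/L
    ph: float
    tp: float  # µg/L
    tn: float  # µg/L
    abundances: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("latitude", "color", "ph", "tp", "tn"):
            value = getattr(self, name)
            _check(
                math.isfinite(value) and value > 0,
                f"{self.lake_id}/{self.site_id}: {name} must be finite and > 0 "
                "(log-transformed downstream)",
            )
        _check(self.ph <= 14.0, f"{self.lake_id}/{self.site_id}: pH above 14")
        counts = dict(self.abundances)
        for taxon, count in counts.items():
            _check(
                int(count) == count and count >= 0,
                f"{self.lake_id}/{self.site_id}: abundance of {taxon} must be a "
                "non-negative integer",
            )
        _check(
            any(c > 0 for c in counts.values()),
            f"{self.lake_id}/{self.site_id}: at least one taxon must be present",
        )
        object.__setattr__(
            self, "abundances", {t: int(c) for t, c in counts.items()}
        )

    @property
    def total_abundance(self) -> int:
        return sum(self.abundances.values())

    @property
    def richness(self) -> int:
        return sum(1 for c in self.abundances.values() if c > 0)


@dataclass(frozen=True)
class CommunityResponses:
    """Per-site community response variables, one value per PUFA where relevant.

    The per-PUFA fields are mappings keyed ``"ara"/"epa"/"dha"``; percentage
    fields are proportions in [0, 1].
    """

    lake_id: str
    site_id: str
    richness: int
    abundance_fa_weighted: Mapping[str, float]
    fa_abundance_weighted: Mapping[str, float]
    fa_x_abundance: Mapping[str, float]
    count_gt3: Mapping[str, int]
    count_gt4: Mapping[str, int]
    pct_gt3: Mapping[str, float]
    pct_gt4: Mapping[str, float]

    def __post_init__(self) -> None:
        _check(self.richness >= 0, "richness must be >= 0")
        for pufa in PUFAS:
            c3, c4 = self.count_gt3[pufa], self.count_gt4[pufa]
            _check(0 <= c4 <= c3 <= self.richness, "count_gt4 <= count_gt3 <= richness")
            for m in (self.pct_gt3, self.pct_gt4):
                _check(0.0 <= m[pufa] <= 1.0, "percentage form must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: no records") from exc
    if frame.empty and len(frame.columns) == 0:
        raise TableFormatError(f"{path}: no records")
    return frame


def _parse_float(token, *, line: int, column: str, path) -> float | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    text = str(token).strip()
    if text in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise TableFormatError(
            f"{path}: line {line}: cannot parse {column}={text!r} as a number"
        ) from exc


def read_taxon_table(path: str | Path) -> list[TaxonPufaProfile]:
    """Read a taxon PUFA table into validated :class:`TaxonPufaProfile` records."""
    path = Path(path)
    frame = _read_csv(path)
    required = ["taxon", "n_lakes"] + [
        f"{kind}_{p}" for p in PUFAS for kind in ("mean", "sd", "class")
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    if len(frame) == 0:
        raise TableFormatError(f"{path}: no records")

    profiles: list[TaxonPufaProfile] = []
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        kwargs: dict = {"taxon": str(row["taxon"]).strip()}
        try:
            kwargs["n_lakes"] = int(str(row["n_lakes"]).strip())
            for pufa in PUFAS:
                mean = _parse_float(row[f"mean_{pufa}"], line=line, column=f"mean_{pufa}", path=path)
                if mean is None:
                    raise TableFormatError(f"{path}: line {line}: missing mean_{pufa}")
                cls = _parse_float(row[f"class_{pufa}"], line=line, column=f"class_{pufa}", path=path)
                if cls is None or int(cls) != cls:
                    raise TableFormatError(f"{path}: line {line}: bad class_{pufa}")
                kwargs[f"mean_{pufa}"] = mean
                kwargs[f"sd_{pufa}"] = _parse_float(row[f"sd_{pufa}"], line=line, column=f"sd_{pufa}", path=path)
                kwargs[f"class_{pufa}"] = int(cls)
            profiles.append(TaxonPufaProfile(**kwargs))
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {line}: {exc}") from exc
    return profiles


def write_taxon_table(profiles: Sequence[TaxonPufaProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row: dict = {"taxon": p.taxon, "n_lakes": p.n_lakes}
        for pufa in PUFAS:
            sd = p.sd_for(pufa)
            row[f"mean_{pufa}"] = f"{p.mean_for(pufa):.10g}"
            row[f"sd_{pufa}"] = "" if sd is None else f"{sd:.10g}"
            row[f"class_{pufa}"] = p.class_for(pufa)
        rows.append(row)
    columns = ["taxon", "n_lakes"] + [
        f"{kind}_{p}" for p in PUFAS for kind in ("mean", "sd", "class")
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def load_reference_profiles() -> list[TaxonPufaProfile]:
    """Load the packaged 24-taxon PUFA reference table (25 Finnish lakes)."""
    with resources.as_file(
        resources.files("pufalakes.data").joinpath("taxon_pufa_profiles.csv")
    ) as path:
        return read_taxon_table(path)


def read_survey(path: str | Path, layout: str = "wide") -> list[SurveySample]:
    """Read a survey table (``wide``: one abundance column per taxon;
    ``long``: one row per site × taxon with ``taxon``/``count`` columns)."""
    path = Path(path)
    frame = _read_csv(path)
    missing = [c for c in SURVEY_FIXED_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")

    def covariates(row: Mapping[str, str], line: int) -> dict:
        out: dict = {
            "lake_id": str(row["lake_id"]).strip(),
            "site_id": str(row["site_id"]).strip(),
            "lake_type": str(row["lake_type"]).strip(),
            "vegetation": str(row["vegetation"]).strip(),
            "substrate": str(row["substrate"]).strip(),
        }
        for name in ("latitude", "color", "ph", "tp", "tn"):
            value = _parse_float(row[name], line=line, column=name, path=path)
            if value is None:
                raise TableFormatError(f"{path}: line {line}: missing {name}")
            out[name] = value
        return out

    samples: list[SurveySample] = []
    if layout == "wide":
        taxon_columns = [c for c in frame.columns if c not in SURVEY_FIXED_COLUMNS]
        if not taxon_columns:
            raise TableFormatError(f"{path}: wide layout has no taxon columns")
        for line, row in enumerate(frame.itertuples(index=False), start=2):
            row = dict(zip(frame.columns, row))
            abundances = {}
            for taxon in taxon_columns:
                count = _parse_float(row[taxon], line=line, column=taxon, path=path)
                abundances[taxon] = 0 if count is None else int(count)
            try:
                samples.append(SurveySample(**covariates(row, line), abundances=abundances))
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {line}: {exc}") from exc
    elif layout == "long":
        for col in ("taxon", "count"):
            if col not in frame.columns:
                raise TableFormatError(f"{path}: long layout requires column {col!r}")
        grouped: dict[tuple[str, str], dict] = {}
        for line, row in enumerate(frame.itertuples(index=False), start=2):
            row = dict(zip(frame.columns, row))
            key = (str(row["lake_id"]).strip(), str(row["site_id"]).strip())
            entry = grouped.setdefault(key, {"cov": covariates(row, line), "abund": {}, "line": line})
            count = _parse_float(row["count"], line=line, column="count", path=path)
            entry["abund"][str(row["taxon"]).strip()] = 0 if count is None else int(count)
        for entry in grouped.values():
            try:
                samples.append(SurveySample(**entry["cov"], abundances=entry["abund"]))
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {entry['line']}: {exc}") from exc
    else:
        raise ValueError(f"unknown survey layout {layout!r}")

    seen: set[tuple[str, str]] = set()
    for s in samples:
        key = (s.lake_id, s.site_id)
        if key in seen:
            raise TableFormatError(f"{path}: duplicate site {key}")
        seen.add(key)
    return samples


def write_survey(
    samples: Sequence[SurveySample],
    path: str | Path,
    layout: str = "wide",
    taxa: Sequence[str] | None = None,
) -> None:
    """Write survey samples back to CSV (inverse of :func:`read_survey`)."""
    if taxa is None:
        universe: list[str] = []
        for s in samples:
            for t in s.abundances:
                if t not in universe:
                    universe.append(t)
        taxa = universe
    float_cols = ("latitude", "color", "ph", "tp", "tn")
    if layout == "wide":
        rows = []
        for s in samples:
            row = {c: getattr(s, c) for c in SURVEY_FIXED_COLUMNS}
            row.update({c: f"{row[c]:.17g}" for c in float_cols})
            for t in taxa:
                row[t] = s.abundances.get(t, 0)
            rows.append(row)
        pd.DataFrame(rows, columns=list(SURVEY_FIXED_COLUMNS) + list(taxa)).to_csv(
            path, index=False
        )
    elif layout == "long":
        rows = []
        for s in samples:
            base = {c: getattr(s, c) for c in SURVEY_FIXED_COLUMNS}
            base.update({c: f"{base[c]:.17g}" for c in float_cols})
            for t in taxa:
                rows.append({**base, "taxon": t, "count": s.abundances.get(t, 0)})
        pd.DataFrame(rows, columns=list(SURVEY_FIXED_COLUMNS) + ["taxon", "count"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown survey layout {layout!r}")


def responses_to_frame(records: Sequence[CommunityResponses]) -> pd.DataFrame:
    """Flatten response records to a table with per-PUFA suffixed columns."""
    rows = []
    for r in records:
        row: dict = {"lake_id": r.lake_id, "site_id": r.site_id, "richness": r.richness}
        for name in (
            "abundance_fa_weighted",
            "fa_abundance_weighted",
            "fa_x_abundance",
            "count_gt3",
            "count_gt4",
            "pct_gt3",
            "pct_gt4",
        ):
            mapping = getattr(r, name)
            for pufa in PUFAS:
                row[f"{name}_{pufa}"] = mapping[pufa]
        rows.append(row)
    columns = ["lake_id", "site_id", "richness"] + [
        f"{name}_{pufa}"
        for name in (
            "abundance_fa_weighted",
            "fa_abundance_weighted",
            "fa_x_abundance",
            "count_gt3",
            "count_gt4",
            "pct_gt3",
            "pct_gt4",
        )
        for pufa in PUFAS
    ]
    return pd.DataFrame(rows, columns=columns)


def write_responses(records: Sequence[CommunityResponses], path: str | Path) -> None:
    responses_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_responses(path: str | Path) -> list[CommunityResponses]:
    frame = _read_csv(path)
    records = []
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        try:
            kwargs: dict = {
                "lake_id": str(row["lake_id"]),
                "site_id": str(row["site_id"]),
                "richness": int(float(row["richness"])),
            }
            for name, caster in (
                ("abundance_fa_weighted", float),
                ("fa_abundance_weighted", float),
                ("fa_x_abundance", float),
                ("count_gt3", lambda v: int(float(v))),
                ("count_gt4", lambda v: int(float(v))),
                ("pct_gt3", float),
                ("pct_gt4", float),
            ):
                kwargs[name] = {p: caster(row[f"{name}_{p}"]) for p in PUFAS}
            records.append(CommunityResponses(**kwargs))
        except (KeyError, ValueError) as exc:
            raise TableFormatError(f"{path}: line {line}: {exc}") from exc
    return records
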