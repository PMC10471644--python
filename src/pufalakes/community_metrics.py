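"""Community-level PUFA response variables.

Given per-site abundance counts ``S_n`` and a per-taxon PUFA score ``FA_n``
(by default the ordinal class 1–5; optionally the mean mass fraction), five
responses are computed per site and per fatty acid:

* ``abundance_fa_weighted`` — Σ S_n·FA_n / Σ FA_n, the community abundance
  weighted by PUFA content; the denominator runs over the full taxon universe
  of the profile table, so it is constant across sites;
* ``fa_abundance_weighted`` — Σ S_n·FA_n / Σ S_n, the abundance-weighted mean
  PUFA score of the community;
* ``fa_x_abundance`` — Σ S_n·FA_n;
* ``count_gt3`` / ``count_gt4`` — number of present taxa in classes {4, 5} /
  {5}, also expressed as proportions of site richness (``pct_gt3``/``pct_gt4``).

Taxa observed in a survey but absent from the profile table either raise an
error (default) or are dropped with a warning, under the caller's policy.
"""

from __future__ import annotations

import warnings
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import PUFAS, CommunityResponses, SurveySample, TaxonPufaProfile

FaScore = Literal["class", "mean"]
MissingPolicy = Literal["error", "drop"]


def _fa_value(profile: TaxonPufaProfile, pufa: str, fa_score: FaScore) -> float:
    if fa_score == "class":
        return float(profile.class_for(pufa))
    if fa_score == "mean":
        return profile.mean_for(pufa)
    raise ValueError(f"unknown fa_score {fa_score!r}")


Community = SurveySample | Mapping[str, int]


def _abundances(sample: Community) -> tuple[dict[str, int], str]:
    """Counts plus a label, from a survey sample or a bare abundance mapping."""
    if isinstance(sample, SurveySample):
        return dict(sample.abundances), f"{sample.lake_id}/{sample.site_id}"
    return dict(sample), "community"


def _resolve(
    sample: Community,
    profiles: Mapping[str, TaxonPufaProfile] | Sequence[TaxonPufaProfile],
    missing: MissingPolicy = "error",
) -> tuple[dict[str, TaxonPufaProfile], dict[str, int]]:
    """Match abundances to profiles, applying the missing-taxon policy."""
    table = (
        dict(profiles)
        if isinstance(profiles, Mapping)
        else {p.taxon: p for p in profiles}
    )
    counts, label = _abundances(sample)
    unknown = sorted(t for t in counts if t not in table)
    if unknown:
        if missing == "error":
            raise KeyError(
                f"{label}: taxa missing from the profile table: {unknown}"
            )
        if missing != "drop":
            raise ValueError(f"unknown missing-taxon policy {missing!r}")
        warnings.warn(
            f"{label}: dropping taxa without profiles: {unknown}",
            stacklevel=3,
        )
        counts = {t: c for t, c in counts.items() if t in table}
    return table, counts


def richness(sample: Community) -> int:
    """Number of taxa with positive abundance at the site."""
    counts, _ = _abundances(sample)
    return sum(1 for c in counts.values() if c > 0)


def abundance_fa_weighted(
    sample: Community,
    profiles: Sequence[TaxonPufaProfile] | Mapping[str, TaxonPufaProfile],
    pufa: str,
    fa_score: FaScore = "class",
    missing: MissingPolicy = "error",
) -> float:
    """Σ S_n·FA_n / Σ FA_n with the denominator over the full taxon universe."""
    table, counts = _resolve(sample, profiles, missing)
    denom = sum(_fa_value(p, pufa, fa_score) for p in table.values())
    if denom <= 0:
        raise ValueError(f"sum of {pufa.upper()} scores over the taxon universe is zero")
    numer = sum(c * _fa_value(table[t], pufa, fa_score) for t, c in counts.items())
    return numer / denom


def fa_abundance_weighted(
    sample: Community,
    profiles: Sequence[TaxonPufaProfile] | Mapping[str, TaxonPufaProfile],
    pufa: str,
    fa_score: FaScore = "class",
    missing: MissingPolicy = "error",
) -> float:
    """Abundance-weighted mean PUFA score, Σ S_n·FA_n / Σ S_n."""
    table, counts = _resolve(sample, profiles, missing)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("undefined weighted mean: community has no individuals")
    numer = sum(c * _fa_value(table[t], pufa, fa_score) for t, c in counts.items())
    return numer / total


def fa_x_abundance(
    sample: Community,
    profiles: Sequence[TaxonPufaProfile] | Mapping[str, TaxonPufaProfile],
    pufa: str,
    fa_score: FaScore = "class",
    missing: MissingPolicy = "error",
) -> float:
    """Σ S_n·FA_n."""
    table, counts = _resolve(sample, profiles, missing)
    return float(sum(c * _fa_value(table[t], pufa, fa_score) for t, c in counts.items()))


def count_rich_taxa(
    sample: Community,
    profiles: Sequence[TaxonPufaProfile] | Mapping[str, TaxonPufaProfile],
    pufa: str,
    threshold: int,
    missing: MissingPolicy = "error",
) -> tuple[int, float]:
    """Count (and richness share) of present taxa with class above ``threshold``.

    ``threshold=3`` counts classes 4 and 5; ``threshold=4`` counts class 5.
    The percentage form is ``count / richness`` (0 for an empty community).
    """
    if threshold not in (3, 4):
        raise ValueError("threshold must be 3 or 4")
    table, counts = _resolve(sample, profiles, missing)
    present = [t for t, c in counts.items() if c > 0]
    count = sum(1 for t in present if table[t].class_for(pufa) > threshold)
    rich = len(present)
    return count, (count / rich if rich > 0 else 0.0)


def community_responses(
    sample: Community,
    profiles: Sequence[TaxonPufaProfile] | Mapping[str, TaxonPufaProfile],
    fa_score: FaScore = "class",
    missing: MissingPolicy = "error",
) -> CommunityResponses:
    """All response variables for one site, for every PUFA."""
    kwargs: dict = {name: {} for name in (
        "abundance_fa_weighted",
        "fa_abundance_weighted",
        "fa_x_abundance",
        "count_gt3",
        "count_gt4",
        "pct_gt3",
        "pct_gt4",
    )}
    for pufa in PUFAS:
        kwargs["abundance_fa_weighted"][pufa] = abundance_fa_weighted(
            sample, profiles, pufa, fa_score, missing
        )
        kwargs["fa_abundance_weighted"][pufa] = fa_abundance_weighted(
            sample, profiles, pufa, fa_score, missing
        )
        kwargs["fa_x_abundance"][pufa] = fa_x_abundance(
            sample, profiles, pufa, fa_score, missing
        )
        c3, p3 = count_rich_taxa(sample, profiles, pufa, 3, missing)
        c4, p4 = count_rich_taxa(sample, profiles, pufa, 4, missing)
        kwargs["count_gt3"][pufa] = c3
        kwargs["count_gt4"][pufa] = c4
        kwargs["pct_gt3"][pufa] = p3
        kwargs["pct_gt4"][pufa] = p4
    return CommunityResponses(
        lake_id=sample.lake_id,
        site_id=sample.site_id,
        richness=sample.richness,
        **kwargs,
    )


def responses_for_survey(
    samples: Sequence[SurveySample],
    profiles: Sequence[TaxonPufaProfile] | Mapping[str, TaxonPufaProfile],
    fa_score: FaScore = "class",
    missing: MissingPolicy = "error",
) -> list[CommunityResponses]:
    return [community_responses(s, profiles, fa_score, missing) for s in samples]


def loglog_richness_regression(
    richness_values: Sequence[float], abundance_values: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of ln(richness) on ln(total abundance): (slope, intercept, r²)."""
    rich = np.asarray(richness_values, dtype=float)
    abund = np.asarray(abundance_values, dtype=float)
    if rich.size != abund.size or rich.size < 3:
        raise ValueError("need at least 3 paired sites")
    if np.any(rich <= 0) or np.any(abund <= 0):
        raise ValueError("richness and abundance must be positive for a log-log fit")
    result = stats.linregress(np.log(abund), np.log(rich))
    r2 = 0.0 if np.isnan(result.rvalue) else float(result.rvalue) ** 2
    return float(result.slope), float(result.intercept), r2
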