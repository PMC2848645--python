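"""Population-level summaries of per-subpopulation genotype observations.

The SNP database reports, for each variant and standard subpopulation, the
percentage of heterozygous carriers, whether substituted homozygotes were
observed, and how many individuals were screened.  This module reduces those
observations to the two per-variant summaries used throughout the package:

* AHP — the average heterozygous population, in percent: the arithmetic mean
  of the non-missing heterozygous percentages.  Missing is distinct from 0;
  a variant screened and never found heterozygous has AHP 0, a variant with
  no usable genotype data has AHP missing.
* homozygote flag — Y / N / unknown, whether any subpopulation reported an
  individual homozygous for the substituted allele.

Observations marked discordant carry unusable genotype calls and are
excluded from both summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class PopulationObservation:
    """One subpopulation's genotype summary for one variant."""

    subpopulation: str
    heterozygous_percent: Optional[float] = None  # [0, 100]
    homozygous_substituted_observed: Optional[bool] = None
    screened_count: Optional[int] = None
    discordant: bool = False

    def __post_init__(self) -> None:
        p = self.heterozygous_percent
        if p is not None and not (0.0 <= p <= 100.0):
            raise ValueError(
                f"heterozygous percent {p!r} outside [0, 100] "
                f"(subpopulation {self.subpopulation!r})"
            )
        if self.screened_count is not None and self.screened_count < 0:
            raise ValueError("screened_count must be non-negative")


def _usable(observations: Iterable[PopulationObservation]):
    return [o for o in observations if not o.discordant]


def compute_ahp(observations: Sequence[PopulationObservation]) -> Optional[float]:
    """Arithmetic mean of non-missing heterozygous percentages.

    Returns None when no subpopulation contributes a usable value.  The mean
    is taken over subpopulations *with* data; subpopulations lacking data do
    not drag the average toward zero.
    """
    values = [
        o.heterozygous_percent
        for o in _usable(observations)
        if o.heterozygous_percent is not None
    ]
    if not values:
        return None
    # fsum: exactly-rounded, so the mean is invariant to observation order
    return math.fsum(values) / len(values)


def homozygote_flag(observations: Sequence[PopulationObservation]) -> str:
    """'Y' if any substituted homozygote was reported, 'N' if data exist and
    none were, 'unknown' otherwise."""
    calls = [
        o.homozygous_substituted_observed
        for o in _usable(observations)
        if o.homozygous_substituted_observed is not None
    ]
    if any(calls):
        return "Y"
    if calls:
        return "N"
    return "unknown"


def build_position_track(annotated, domain_model):
    """Per-position AHP series plus the domain interval track.

    ``annotated`` is a sequence of AnnotatedVariant.  In the plotted series a
    missing AHP is rendered as 0 (unknown and zero are conflated only for
    plotting); the underlying data value stays missing (NaN).  Unmappable
    records have no reference position and are omitted from the series.

    Returns ``(series, domain_track)`` where ``series`` is a DataFrame with
    columns position / plot_value / data_value / label and ``domain_track``
    is a list of ``{"name", "group", "start", "end"}`` interval dicts.
    """
    rows = []
    for av in annotated:
        pos = av.mapped.reference_position
        if pos is None:
            continue
        rows.append(
            {
                "position": pos,
                "plot_value": 0.0 if av.ahp is None else av.ahp,
                "data_value": float("nan") if av.ahp is None else av.ahp,
                "label": av.record.substitution_label(),
            }
        )
    series = pd.DataFrame(rows, columns=["position", "plot_value", "data_value", "label"])
    series = series.sort_values("position", kind="stable").reset_index(drop=True)

    domain_track = []
    for dom in domain_model.domains:
        for start, end in dom.intervals:
            domain_track.append(
                {"name": dom.name, "group": dom.group, "start": start, "end": end}
            )
    return series, domain_track
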