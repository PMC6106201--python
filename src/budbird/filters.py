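"""Inclusion rules applied to a count dataset before modelling.

For a single species: routes on which the species was never detected are
dropped; a stratum is kept only if at least three detected routes remain
and the mean number of detection years per retained route is at least 4
(boundary inclusive). The occupancy proportion z_i — the fraction of all
surveyed routes in the stratum with at least one detection — is computed
on the pre-filter route universe, because it is later used to scale
route-conditional predicted means up to all routes in the stratum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["InclusionReport", "filter_routes"]

MIN_ROUTES_PER_STRATUM = 3
MIN_MEAN_DETECTION_YEARS = 4.0


@dataclass
class InclusionReport:
    """What survived filtering, and the per-stratum occupancy z_i."""

    retained_routes: set = field(default_factory=set)
    retained_strata: set = field(default_factory=set)
    routes_per_stratum: dict = field(default_factory=dict)
    mean_detection_years: dict = field(default_factory=dict)
    z_by_stratum: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained_routes": sorted(self.retained_routes),
                "retained_strata": sorted(self.retained_strata),
                "routes_per_stratum": {str(k): v for k, v in self.routes_per_stratum.items()},
                "mean_detection_years": {str(k): v for k, v in self.mean_detection_years.items()},
                "z_by_stratum": {str(k): v for k, v in self.z_by_stratum.items()},
            }
        )


def filter_routes(counts: pd.DataFrame) -> tuple[pd.DataFrame, InclusionReport]:
    """Apply the species inclusion rules; return retained rows and a report.

    ``counts`` needs columns (stratum, route, year, count). The returned
    frame keeps the input's columns and row order. z_by_stratum is
    reported for every input stratum (before any removal); the remaining
    report fields describe retained strata only.
    """
    report = InclusionReport()
    if counts.empty:
        return counts.copy(), report

    per_route = counts.groupby(["stratum", "route"]).agg(
        total=("count", "sum"),
        detection_years=("count", lambda c: int((c > 0).sum())),
    )
    detected = per_route["total"] > 0

    for stratum, grp in per_route.groupby(level="stratum"):
        det = detected.loc[stratum]
        report.z_by_stratum[stratum] = float(det.mean())

    retained_strata = []
    for stratum, grp in per_route[detected].groupby(level="stratum"):
        n_routes = len(grp)
        mean_years = float(grp["detection_years"].mean())
        if n_routes >= MIN_ROUTES_PER_STRATUM and mean_years >= MIN_MEAN_DETECTION_YEARS:
            retained_strata.append(stratum)
            report.routes_per_stratum[stratum] = n_routes
            report.mean_detection_years[stratum] = mean_years

    report.retained_strata = set(retained_strata)
    keep_routes = per_route[detected].loc[
        per_route[detected].index.get_level_values("stratum").isin(report.retained_strata)
    ]
    report.retained_routes = set(keep_routes.index.get_level_values("route"))

    key = pd.MultiIndex.from_frame(counts[["stratum", "route"]])
    mask = key.isin(keep_routes.index)
    return counts[mask].copy(), report
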