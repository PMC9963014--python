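"""Multi-date vegetation-cover change analysis.

Given co-registered fractional-cover maps for an ordered sequence of dates
(all produced with the same index), this module summarizes the mean cover
and the per-grade area shares per date, and differences pairs of maps to
localize change: negative differences flag degradation, positive ones
recovery.  No temporal smoothing or trend fitting is applied — the series is
reported raw; plotting is a thin convenience on top of the CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dichotomy import FVCMap, GradeScheme, grade_area_fractions, grade_map, mean_fvc
from .errors import ContractError
from .indices import IndexDefinition

__all__ = ["DateSeries", "DifferenceMap", "series_summary", "change_map"]


@dataclass
class DifferenceMap:
    """Per-pixel cover change (later minus earlier), in [-1, 1]."""

    values: np.ndarray
    valid_mask: np.ndarray
    georeference: tuple | None = None


@dataclass
class DateSeries:
    """Ordered per-date mean cover and grade-area shares."""

    entries: list[tuple[str, float, dict[int, float]]]
    index: IndexDefinition | None = None
    scheme: GradeScheme | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for date, mean, shares in self.entries:
            row: dict = {"date": date, "mean_fvc": mean}
            for code, share in shares.items():
                row[f"grade_{code}_share"] = share
            rows.append(row)
        return pd.DataFrame(rows)

    def plot(self, path: str) -> str:
        """Line chart of mean cover over the dates (convenience output)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        dates = [e[0] for e in self.entries]
        means = [e[1] for e in self.entries]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.plot(dates, means, marker="o")
        ax.set_xlabel("date")
        ax.set_ylabel("mean fractional vegetation cover")
        ax.set_ylim(0, 1)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path


def series_summary(scenes: Mapping[str, FVCMap],
                   scheme: GradeScheme | str = "six_level") -> DateSeries:
    """Per-date mean cover and grade-area shares for an ordered scene mapping.

    All maps must come from the same index (mixing models across dates would
    make the series incomparable).
    """
    if not scenes:
        raise ContractError("no scenes given")
    if isinstance(scheme, str):
        scheme = GradeScheme.by_name(scheme)
    index = None
    entries = []
    for date, fvc in scenes.items():
        if fvc.endpoints is not None:
            if index is None:
                index = fvc.endpoints.index
            elif fvc.endpoints.index.name != index.name:
                raise ContractError(
                    f"mixed indices in series: {index.name} vs {fvc.endpoints.index.name}"
                )
        shares = grade_area_fractions(grade_map(fvc, scheme))
        entries.append((str(date), mean_fvc(fvc), shares))
    return DateSeries(entries=entries, index=index, scheme=scheme)


def change_map(earlier: FVCMap, later: FVCMap) -> DifferenceMap:
    """Pixelwise cover change, later minus earlier, on jointly valid pixels."""
    if earlier.shape != later.shape:
        raise ContractError("scene dimensions differ")
    joint = earlier.valid_mask & later.valid_mask
    diff = np.where(joint, later.values - earlier.values, np.nan)
    return DifferenceMap(values=diff, valid_mask=joint,
                         georeference=later.georeference or earlier.georeference)
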