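"""Region-aware particle fate accounting and deposition metrics.

Deposition efficiency and deposition fraction for a region r are

    DE_r = 100 * (mass deposited in r) / (mass that entered r)
    DF_r = 100 * (mass deposited in r) / (mass released)

Mass is carried per tracked particle as its size-bin mass weight divided
by the bin count, so both metrics are mass-based.  Particles exiting the
domain are booked to the terminal filter region, which makes the regional
DFs sum to exactly 100% for any completed run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "RegionMap",
    "DepositionTally",
    "deposition_efficiency",
    "deposition_fraction",
    "tally_frame",
]


@dataclass(frozen=True)
class Region:
    """A wall region along the flow path."""

    name: str
    behavior: str = "trap"            # "trap" | "reflect"
    yplus_limit: float | None = None  # per-region override, wall units

    def __post_init__(self) -> None:
        if self.behavior not in ("trap", "reflect"):
            raise ValueError(f"unknown wall behavior {self.behavior!r}")


class RegionMap:
    """Ordered wall regions along the flow path plus one terminal outlet.

    ``boundaries`` are the arc-length coordinates separating consecutive
    regions; region i covers [boundaries[i-1], boundaries[i]).  The
    terminal region (the filter) receives all escaping mass and has no
    wall of its own.
    """

    def __init__(
        self,
        regions: list[Region],
        boundaries: list[float],
        terminal: str = "filter",
    ) -> None:
        if len(boundaries) != len(regions):
            raise ValueError("need one upper boundary per wall region")
        if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
            raise ValueError("region boundaries must be strictly increasing")
        names = [r.name for r in regions] + [terminal]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        self.regions = list(regions)
        self.boundaries = [float(b) for b in boundaries]
        self.terminal = terminal

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions] + [self.terminal]

    @property
    def path_end(self) -> float:
        return self.boundaries[-1]

    def region_index(self, s) -> np.ndarray:
        """Wall-region index for arc-length coordinate(s) s (clipped)."""
        return np.minimum(
            np.searchsorted(self.boundaries, np.asarray(s, dtype=float), "right"),
            len(self.regions) - 1,
        )

    def behavior_codes(self) -> np.ndarray:
        """1 where the wall traps, 0 where it reflects (per wall region)."""
        return np.array(
            [1 if r.behavior == "trap" else 0 for r in self.regions], dtype=np.int8
        )


class DepositionTally:
    """Per-region trapped/entered mass accounting for one run."""

    def __init__(self, region_names: list[str], terminal: str) -> None:
        if terminal not in region_names:
            raise ValueError("terminal region must be listed")
        self.region_names = list(region_names)
        self.terminal = terminal
        self.deposited: dict[str, float] = {n: 0.0 for n in region_names}
        self.entered: dict[str, float] = {n: 0.0 for n in region_names}
        self.released: float = 0.0
        self.unfinished: float = 0.0

    def add_release(self, mass: float) -> None:
        self.released += mass

    def add_entry(self, region: str, mass: float) -> None:
        self.entered[region] += mass

    def add_deposit(self, region: str, mass: float) -> None:
        self.deposited[region] += mass

    def book_escaped(self, mass: float) -> None:
        """Escaping mass deposits on the terminal filter."""
        self.entered[self.terminal] += mass
        self.deposited[self.terminal] += mass

    def add_unfinished(self, mass: float) -> None:
        self.unfinished += mass

    @property
    def total_deposited(self) -> float:
        return sum(self.deposited.values())

    def conservation_error(self) -> float:
        """|released - (deposited + unfinished)| / released."""
        if self.released == 0:
            return 0.0
        return abs(
            self.released - self.total_deposited - self.unfinished
        ) / self.released

    def check_conservation(self, rtol: float = 1e-9) -> None:
        err = self.conservation_error()
        if err > rtol or self.unfinished > 0:
            raise RuntimeError(
                f"mass conservation failure: relative error {err:.3e}, "
                f"unfinished mass {self.unfinished:.3e}"
            )


def deposition_efficiency(tally: DepositionTally, region: str) -> float:
    """DE_r in percent; errors if the region was never entered."""
    entered = tally.entered[region]
    if entered <= 0:
        raise ZeroDivisionError(
            f"deposition efficiency undefined: no mass entered {region!r}"
        )
    return 100.0 * tally.deposited[region] / entered


def deposition_fraction(tally: DepositionTally, region: str) -> float:
    """DF_r in percent of the released mass."""
    if tally.released <= 0:
        raise ZeroDivisionError("no mass released")
    return 100.0 * tally.deposited[region] / tally.released


def tally_frame(tally: DepositionTally) -> pd.DataFrame:
    """Tally as a frame: rows = regions; entered, deposited, DE%, DF%."""
    rows = []
    for name in tally.region_names:
        entered = tally.entered[name]
        rows.append(
            {
                "region": name,
                "mass_entered": entered,
                "mass_deposited": tally.deposited[name],
                "DE_percent": (
                    100.0 * tally.deposited[name] / entered if entered > 0 else np.nan
                ),
                "DF_percent": deposition_fraction(tally, name),
            }
        )
    return pd.DataFrame(rows).set_index("region")
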