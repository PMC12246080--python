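"""Probe-set coverage arithmetic and design validation for bDNA smFISH.

Each mitochondrial mRNA is targeted by pairs of primary probes; both probes
of a pair hybridize to adjacent regions of 20 to 30 nucleotides, so one
pair occupies between 40 and 60 nt of the transcript.  Transcript coverage
is the fraction of the transcript occupied by probe pairs, printed as an
integer percentage (rounded half away from zero, which reproduces the
published design table exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: bounds on the mean transcript footprint of one probe pair (two 20-30 nt
#: hybridization regions)
FOOTPRINT_RANGE_NT = (40.0, 60.0)


@dataclass
class ProbeSetDesign:
    """One probe set: transcript, its length, pair count and covered nt."""

    transcript: str
    length_nt: int
    n_pairs: int
    covered_nt: int

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not (0 <= self.covered_nt <= max(self.length_nt, 0)):
            # tolerated at construction so validate_design can report it
            pass


@dataclass
class DesignReport:
    """Validation outcome: list of rule violations (empty means valid)."""

    design: ProbeSetDesign
    mean_footprint_nt: float | None
    violations: list[str]

    @property
    def valid(self) -> bool:
        return not self.violations


def coverage_percent(d: ProbeSetDesign) -> int:
    """Transcript coverage as an integer percent, half rounded away from zero."""
    if d.length_nt <= 0:
        raise ValueError("transcript length must be positive")
    pct = 100.0 * d.covered_nt / d.length_nt
    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))


def validate_design(d: ProbeSetDesign) -> DesignReport:
    """Check a probe-set design against the pairing rules.

    Flags coverage exceeding the transcript length, covered nucleotides
    without any probe pair, and a mean per-pair footprint outside 40-60 nt.
    """
    violations: list[str] = []
    if d.covered_nt > d.length_nt:
        violations.append(
            f"covered_nt {d.covered_nt} exceeds transcript length {d.length_nt}")
    if d.covered_nt < 0:
        violations.append("covered_nt is negative")
    if d.n_pairs == 0:
        mean_fp = None
        if d.covered_nt > 0:
            violations.append("covered_nt > 0 with zero probe pairs")
    else:
        mean_fp = d.covered_nt / d.n_pairs
        lo, hi = FOOTPRINT_RANGE_NT
        if not (lo <= mean_fp <= hi):
            violations.append(
                f"mean footprint {mean_fp:.1f} nt/pair outside [{lo:.0f}, {hi:.0f}]")
    return DesignReport(design=d, mean_footprint_nt=mean_fp,
                        violations=violations)


def load_probe_table(path=None) -> pd.DataFrame:
    """Load a probe-design table (default: the packaged mitochondrial set)."""
    if path is None:
        with resources.files("mitofish").joinpath("data/table1.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def designs_from_table(table: pd.DataFrame) -> list[ProbeSetDesign]:
    return [ProbeSetDesign(transcript=row.transcript,
                           length_nt=int(row.length_nt),
                           n_pairs=int(row.n_pairs),
                           covered_nt=int(row.covered_nt))
            for row in table.itertuples(index=False)]
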