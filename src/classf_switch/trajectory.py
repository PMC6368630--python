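"""Inter-residue distance metrics over MD-style trajectories.

The activation-related coordinate used for Class F receptors is the
TM3-TM6 distance (here between residues 3.50 and 6.34): a larger distance
indicates a more open, active-like conformation of the cytoplasmic bundle.
This module extracts per-frame distances from multi-frame structures (or
accepts precomputed distance tables), bins them into normalized
distributions, condenses each replicate into a scalar metric (minimum
distance, or fraction of frames below a threshold), and compares conditions
with an unpaired pooled-variance Student t test (the printed df of
n1 + n2 - 2 identifies the pooled, not Welch, test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import StructureModel
from .generic_numbering import GenericLabel

__all__ = [
    "Trajectory",
    "DistanceSeries",
    "TestResult",
    "distance_series",
    "distance_distribution",
    "replicate_metrics",
    "compare_conditions",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a statistical test (shared with the pharmacology module)."""

    statistic_name: str  # "t" or "F"
    statistic: float
    df: int | tuple[int, int]
    p: float
    tails: str = "two"


@dataclass
class Trajectory:
    """An ordered list of structure frames for one simulation replicate."""

    replicate_id: str
    condition: str
    frames: list[StructureModel]
    frame_interval: float | None = None  # time units, optional

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")


@dataclass
class DistanceSeries:
    """Per-frame distance (A) between a residue pair in one replicate."""

    replicate_id: str
    condition: str
    res_a: str
    res_b: str
    atom_rule: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty distance series")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("distances must be positive and finite")


def _resolve_atoms(frame: StructureModel, label: GenericLabel, atom_rule: str):
    """Coordinates participating in the distance for one residue."""
    if frame.segment_map is None:
        raise ValueError(f"frame {frame.structure_id} has no segment map")
    res_index = frame.segment_map.label_to_position(label)
    atoms = [a for a in frame.atoms if a.res_index == res_index and a.is_heavy]
    if atom_rule == "CA":
        atoms = [a for a in atoms if a.atom_name == "CA"]
    elif atom_rule == "sidechain_centroid":
        side = [a for a in atoms if a.atom_name not in ("N", "CA", "C", "O")]
        atoms = side or [a for a in atoms if a.atom_name == "CA"]
    elif atom_rule != "heavy_min":
        raise ValueError(f"unknown atom_rule {atom_rule!r}")
    if not atoms:
        raise ValueError(
            f"residue {label} (resSeq {res_index}) unresolvable in frame "
            f"{frame.structure_id} under rule {atom_rule!r}"
        )
    return np.array([a.coords for a in atoms], dtype=float)


def distance_series(
    traj: Trajectory,
    res_a: GenericLabel | str,
    res_b: GenericLabel | str,
    atom_rule: str = "CA",
) -> DistanceSeries:
    """Per-frame Euclidean distance between two residues.

    ``atom_rule`` selects the atoms: "CA" (default, Calpha-Calpha),
    "heavy_min" (closest heavy-atom pair per frame), or
    "sidechain_centroid" (centroid of side-chain heavy atoms, falling back
    to Calpha for glycine-like residues).
    """
    la = GenericLabel.parse(res_a) if isinstance(res_a, str) else res_a
    lb = GenericLabel.parse(res_b) if isinstance(res_b, str) else res_b
    values = []
    for i, frame in enumerate(traj.frames):
        try:
            ca = _resolve_atoms(frame, la, atom_rule)
            cb = _resolve_atoms(frame, lb, atom_rule)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
        if atom_rule == "heavy_min":
            values.append(float(d.min()))
        elif atom_rule == "sidechain_centroid":
            values.append(float(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0))))
        else:
            values.append(float(d[0, 0]))
    return DistanceSeries(
        traj.replicate_id, traj.condition, str(la), str(lb), atom_rule,
        np.array(values),
    )


def distance_distribution(
    series: DistanceSeries | np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of a distance series.

    Bin edges are multiples of ``bin_width`` starting at
    floor(min/bin_width)*bin_width, half-open [lo, hi) except that the top
    edge is chosen past the maximum so every value falls in a bin.  Returns
    (edges, frequencies) with frequencies summing to 1.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series)
    if values.size == 0:
        raise ValueError("empty series")
    lo = np.floor(values.min() / bin_width) * bin_width
    n_bins = int(np.floor((values.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts / values.size


def replicate_metrics(
    series_set: list[DistanceSeries], threshold: float
) -> pd.DataFrame:
    """Scalar summaries per replicate.

    For each series: min_distance, fraction_below (frames strictly below
    ``threshold``), fraction_above (at-or-above; the two sum to 1).
    Returns a tidy DataFrame (replicate_id, condition, metric, threshold,
    value).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    rows = []
    for s in series_set:
        frac_below = float(np.mean(s.values < threshold))
        for metric, value, thr in (
            ("min_distance", float(s.values.min()), np.nan),
            ("fraction_below", frac_below, threshold),
            ("fraction_above", 1.0 - frac_below, threshold),
        ):
            rows.append(
                {
                    "replicate_id": s.replicate_id,
                    "condition": s.condition,
                    "metric": metric,
                    "threshold": thr,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def compare_conditions(metrics_a, metrics_b) -> TestResult:
    """Unpaired two-tailed Student t test with pooled variance.

    df = n_a + n_b - 2 (with the Fig.-style n = 3 vs 4 this gives df = 5).
    Identical constant groups give t = 0, p = 1; zero pooled variance with
    unequal means is an error.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2 (got {a.size} and {b.size})")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return TestResult("t", 0.0, df, 1.0)
        raise ValueError("degenerate variance: zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult("t", float(t), df, max(p, np.finfo(float).tiny))
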