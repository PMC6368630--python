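"""Cancer-vs-population variation scoring at generic residue positions.

Somatic (cancer) and germ-line (population) missense variant counts are
aggregated per generic label across a receptor family, and each position i
receives a relative variation score

    RelVar_i = ln( (CV_i / max_j CV_j + 1) / (NV_i / max_j NV_j + 1) )

where CV_i is the cancer variant count and NV_i the naturally occurring
(population) variant count at position i, each max-normalized over all
positions.  Positive scores flag positions with an excess of cancer
variation relative to the healthy population; because normalized counts lie
in [0, 1], RelVar is bounded by +/- ln 2.

Per-column conservation of an alignment is scored as 1 - H/ln(20), with H
the Shannon entropy (natural log) of the amino-acid frequencies in the
column, gaps excluded.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generic_numbering import GenericLabel, SegmentMap, UnmappedPositionError

__all__ = [
    "VariantRecord",
    "AMINO_ACIDS",
    "count_variants",
    "relvar",
    "rank_hotspots",
    "conservation",
    "DegenerateNormalizerError",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

RELVAR_BOUND = math.log(2.0)


class DegenerateNormalizerError(ValueError):
    """Raised when a count table is all-zero, so max-normalization is undefined."""


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant observation (or aggregated count) at a position."""

    receptor_id: str
    position: int
    ref_aa: str
    alt_aa: str
    count: int = 1
    source: str = "cancer"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


def _records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    return [
        VariantRecord(
            receptor_id=str(r.receptor_id),
            position=int(r.position),
            ref_aa=str(r.ref_aa),
            alt_aa=str(r.alt_aa),
            count=int(r.count),
            source=str(r.source),
        )
        for r in df.itertuples(index=False)
    ]


def count_variants(
    records: Iterable[VariantRecord] | pd.DataFrame,
    maps: Mapping[str, SegmentMap],
    source: str,
) -> tuple[pd.Series, pd.DataFrame, Counter]:
    """Aggregate variant counts per generic label.

    Only missense records (ref != alt, both standard amino acids) at mapped
    positions are counted; everything else is tallied in the skip report so
    that input mass is conserved:
    sum(family counts) + sum(skip counts) == sum(record counts).

    Parameters
    ----------
    records
        Variant records, or a DataFrame with columns receptor_id, position,
        ref_aa, alt_aa, count, source.
    maps
        receptor_id -> SegmentMap for every receptor that may appear.
    source
        Which records to count ("cancer" or "population"); records with a
        different source are ignored entirely (not part of the mass balance).

    Returns
    -------
    family : pd.Series
        Counts per generic label (string form), summed over receptors,
        covering the union of all labels in ``maps`` (zeros included).
    per_receptor : pd.DataFrame
        label x receptor_id count matrix.
    skipped : Counter
        Skipped record mass by reason: "unmapped_position",
        "not_missense".
    """
    if isinstance(records, pd.DataFrame):
        records = _records_from_frame(records)
    records = [r for r in records if r.source == source]

    unknown = sorted({r.receptor_id for r in records} - set(maps))
    if unknown:
        raise KeyError(f"no SegmentMap for receptor id(s): {', '.join(unknown)}")

    all_labels = sorted({str(l) for m in maps.values() for l in m.labels()})
    receptor_ids = sorted(maps)
    per_receptor = pd.DataFrame(
        0, index=pd.Index(all_labels, name="label"), columns=receptor_ids
    )
    skipped: Counter = Counter()

    for rec in records:
        is_missense = (
            rec.ref_aa in AMINO_ACIDS
            and rec.alt_aa in AMINO_ACIDS
            and rec.ref_aa != rec.alt_aa
        )
        if not is_missense:
            skipped["not_missense"] += rec.count
            continue
        try:
            label = maps[rec.receptor_id].assign_label(rec.position)
        except UnmappedPositionError:
            skipped["unmapped_position"] += rec.count
            continue
        per_receptor.loc[str(label), rec.receptor_id] += rec.count

    family = per_receptor.sum(axis=1)
    family.name = source
    return family, per_receptor, skipped


def relvar(
    cancer_counts: pd.Series | Mapping[str, int],
    population_counts: pd.Series | Mapping[str, int],
) -> pd.DataFrame:
    """Sitewise relative variation score from per-label count tables.

    Both tables must be defined on the same label set.  Returns a DataFrame
    indexed by label with columns CV, NV, relvar, where
    relvar = ln((CV/max CV + 1) / (NV/max NV + 1)).

    Raises :class:`DegenerateNormalizerError` if either table is all-zero
    (max-normalizer undefined).
    """
    cv = pd.Series(cancer_counts, dtype=float).sort_index()
    nv = pd.Series(population_counts, dtype=float).sort_index()
    if not cv.index.equals(nv.index):
        raise ValueError("cancer and population tables must share the same label set")
    if (cv < 0).any() or (nv < 0).any():
        raise ValueError("counts must be non-negative")
    max_cv, max_nv = cv.max(), nv.max()
    if max_cv == 0 or max_nv == 0:
        raise DegenerateNormalizerError(
            "degenerate normalizer: all-zero cancer or population table"
        )
    score = np.log((cv / max_cv + 1.0) / (nv / max_nv + 1.0))
    out = pd.DataFrame({"CV": cv.astype(int), "NV": nv.astype(int), "relvar": score})
    out.index.name = "label"
    return out


def rank_hotspots(scores: pd.DataFrame, k: int) -> list[str]:
    """Top-k labels by relative variation score.

    Sorted by relvar descending; ties broken by higher cancer count CV, then
    lexicographic label.  If k exceeds the number of positions, all
    positions are returned.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    df = scores.reset_index()
    df = df.sort_values(
        by=["relvar", "CV", "label"], ascending=[False, False, True], kind="mergesort"
    )
    return df["label"].head(k).tolist()


def conservation(
    msa,
    labels: Mapping[int, GenericLabel | str] | None = None,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-column conservation of an alignment.

    score_c = 1 - H_c / ln(20), H_c the Shannon entropy (natural log) of the
    amino-acid frequencies in column c with gaps excluded.  A fully
    conserved column scores 1; a column uniform over the 20 amino acids
    scores 0.

    Parameters
    ----------
    msa
        ``Bio.Align.MultipleSeqAlignment`` or mapping id -> gapped sequence.
    labels
        Optional 1-based column -> generic label annotation.
    min_coverage
        Columns with a smaller fraction of non-gap characters are flagged
        ``covered=False`` (score still reported when any residue is present).

    Returns
    -------
    DataFrame with columns column (1-based), label, score, n_sequences,
    covered.
    """
    if hasattr(msa, "items"):
        seqs = [str(v) for v in msa.values()]
    else:
        seqs = [str(rec.seq) for rec in msa]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    n_total = len(seqs)

    rows = []
    for c in range(length):
        column = [s[c] for s in seqs if s[c] != "-"]
        n = len(column)
        if n == 0:
            score = float("nan")
        else:
            counts = Counter(column)
            freqs = np.array([v / n for v in counts.values()])
            entropy = float(-(freqs * np.log(freqs)).sum())
            score = 1.0 - entropy / math.log(20.0)
        label = labels.get(c + 1) if labels else None
        rows.append(
            {
                "column": c + 1,
                "label": str(label) if label is not None else "",
                "score": score,
                "n_sequences": n,
                "covered": n / n_total >= min_coverage,
            }
        )
    return pd.DataFrame(rows)
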