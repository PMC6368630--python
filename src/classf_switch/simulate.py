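"""Seeded synthetic-data generators for every pipeline stage.

Real inputs to the analyses — family-wide variant tables from cancer and
population genomics, crystal-structure ensembles, MD trajectories, BRET
concentration-response curves — cannot be bundled or downloaded, so each
generator here emits data with the statistical structure the corresponding
stage assumes, with the planted ground truth returned alongside (and
embedded as header metadata when written to disk) so recovery tests are
self-contained.

All generators run off a single ``numpy.random.default_rng(seed)``: the
same (seed, config) is byte-reproducible, and changing the seed changes the
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import AtomRecord, StructureModel
from .generic_numbering import GenericLabel, HelixSegment, SegmentMap

__all__ = [
    "gen_msa",
    "gen_variant_tables",
    "gen_helix_bundle",
    "gen_trajectories",
    "gen_dose_response",
    "default_family_map",
    "series_from_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ------------------------------------------------------------------ MSA

def gen_msa(
    n_seqs: int,
    length: int,
    conserved_columns: dict[int, float | tuple[float, int]] | None = None,
    gap_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Alignment with controlled per-column conservation.

    ``conserved_columns`` maps 1-based column -> conservation level (the
    probability of the column's consensus residue); the remaining mass is
    spread uniformly over ``n_alt`` alternative residues (default 19, i.e.
    all others).  A value may be given as ``(level, n_alt)`` — e.g.
    ``(0.5, 1)`` yields the two-residue 50/50 column whose conservation
    score is 1 - ln2/ln20.  Unlisted columns draw uniformly from the 20
    amino acids.  Returns {seq_id: aligned_sequence}.
    """
    conserved_columns = conserved_columns or {}
    for col in conserved_columns:
        if not 1 <= col <= length:
            raise ValueError(f"conserved column {col} outside 1..{length}")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    # per-column residue probabilities
    probs = np.full((length, 20), 1.0 / 20.0)
    for col, spec in conserved_columns.items():
        level, n_alt = spec if isinstance(spec, tuple) else (spec, 19)
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"conservation level must be in [0,1], got {level}")
        if not 1 <= n_alt <= 19:
            raise ValueError(f"n_alt must be in 1..19, got {n_alt}")
        order = rng.permutation(20)
        p = np.zeros(20)
        p[order[0]] = level
        p[order[1 : n_alt + 1]] = (1.0 - level) / n_alt
        probs[col - 1] = p

    cum = probs.cumsum(axis=1)
    draws = rng.random((n_seqs, length))
    idx = (draws[:, :, None] > cum[None, :, :]).sum(axis=2)
    chars = aa[idx]
    if gap_fraction > 0:
        gaps = rng.random((n_seqs, length)) < gap_fraction
        chars = np.where(gaps, "-", chars)
    width = len(str(n_seqs))
    return {
        f"seq{str(i + 1).zfill(width)}": "".join(row) for i, row in enumerate(chars)
    }


# ------------------------------------------------------------ variant tables

def default_family_map(
    receptor_id: str = "SYNF1", n_positions: int = 50, offset_start: int = 28
) -> SegmentMap:
    """A synthetic 7-helix receptor map with ``n_positions`` labelled sites.

    Positions are distributed over helices 1-7 (residue index = 100*helix +
    offset, a readable synthetic numbering); with the default 50 positions
    helix 6 spans offsets 28-34, so the 6.32 hotspot position exists.
    """
    per_helix = [n_positions // 7] * 7
    for h in range(n_positions % 7):
        per_helix[h] += 1
    segments = []
    for h, count in enumerate(per_helix, start=1):
        if count == 0:
            continue
        segments.append(
            HelixSegment(
                helix=h,
                seq_start=100 * h + offset_start,
                seq_end=100 * h + offset_start + count - 1,
                label_start=GenericLabel(h, offset_start),
            )
        )
    return SegmentMap(receptor_id, tuple(segments))


def gen_variant_tables(
    segmap: SegmentMap | None = None,
    hotspot: str = "6.32",
    enrichment: float = 10.0,
    base_rate: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SegmentMap, dict]:
    """Cancer and population variant tables with one planted hotspot.

    Per-position counts are Poisson(base_rate) in both tables, except the
    hotspot's cancer count which is Poisson(enrichment * base_rate).  The
    default map has 50 positions across 7 helices (matching a desk-scale
    receptor family scan); the paper-scale cohort sizes are deliberately not
    emulated — only the enrichment structure matters to the score.

    Returns (cancer_table, population_table, segmap, ground_truth); the
    tables have columns receptor_id, position, ref_aa, alt_aa, count,
    source.
    """
    if enrichment < 1:
        raise ValueError(f"enrichment must be >= 1, got {enrichment}")
    segmap = segmap or default_family_map()
    labels = [str(l) for l in segmap.labels()]
    if hotspot not in labels:
        raise ValueError(f"hotspot {hotspot} not among the map's labels")
    rng = np.random.default_rng(seed)

    def _table(source: str) -> pd.DataFrame:
        rows = []
        for label in labels:
            pos = segmap.label_to_position(label)
            rate = base_rate
            if source == "cancer" and label == hotspot:
                rate = enrichment * base_rate
            count = int(rng.poisson(rate))
            ref, alt = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
            rows.append(
                {
                    "receptor_id": segmap.receptor_id,
                    "position": pos,
                    "ref_aa": ref,
                    "alt_aa": alt,
                    "count": count,
                    "source": source,
                }
            )
        return pd.DataFrame(rows)

    truth = {
        "hotspot": hotspot,
        "enrichment": enrichment,
        "base_rate": base_rate,
        "seed": seed,
    }
    return _table("cancer"), _table("population"), segmap, truth


# ------------------------------------------------------------- helix bundle

_HELIX_RADIUS = 2.3  # A, Calpha helix radius
_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = math.radians(100.0)  # per residue


def gen_helix_bundle(
    n_helices: int = 7,
    residues_per_helix: int = 40,
    planted_contacts: list[tuple[str, str]] | None = None,
    seed: int = 0,
    spacing: float = 12.2,
    offset_start: int = 24,
    contact_gap: float = 4.0,
    cutoff: float = 4.5,
    clearance: float = 0.5,
    jitter: float = 0.05,
    structure_id: str = "BUNDLE",
) -> StructureModel:
    """An idealized 7-helix pseudo-atom bundle with planted contacts.

    Helices are ideal Calpha traces (2.3 A radius, 1.5 A rise, 100 deg
    twist) on a circle with adjacent axes ``spacing`` apart, alternating
    direction (antiparallel, as in a real TM bundle) so residues with
    matched generic offsets on neighboring helices sit at similar heights.
    Helix h residue with offset o has resSeq 100*h + o and label h.o;
    offsets run ``offset_start`` .. ``offset_start + residues_per_helix-1``.

    For each planted label pair a pseudo side-chain atom ("CB") is placed
    on each residue along the inter-residue line so the atom pair sits
    exactly ``contact_gap`` apart (< cutoff).  After construction the
    generator verifies that every NON-planted inter-helix residue pair
    stays farther than ``cutoff + clearance`` and raises on geometric
    infeasibility, so the planted set is exactly the detectable
    interhelical contact set.  ``jitter`` adds a small seeded coordinate
    perturbation (applied before pseudo-atom placement) so distinct seeds
    give distinct structures without disturbing the geometry guarantees.
    """
    planted_contacts = planted_contacts or []
    rng = np.random.default_rng(seed)
    R = spacing / (2.0 * math.sin(math.pi / n_helices))
    top = offset_start + residues_per_helix - 1

    segments = tuple(
        HelixSegment(
            helix=h,
            seq_start=100 * h + offset_start,
            seq_end=100 * h + top,
            label_start=GenericLabel(h, offset_start),
        )
        for h in range(1, n_helices + 1)
    )
    segmap = SegmentMap(structure_id, segments)

    for la, lb in planted_contacts:
        for l in (la, lb):
            lab = GenericLabel.parse(l)
            if lab.helix > n_helices or not (offset_start <= lab.offset <= top):
                raise ValueError(f"planted label {l} does not exist in the bundle")

    ca: dict[int, np.ndarray] = {}  # resSeq -> Calpha coords
    for h in range(1, n_helices + 1):
        angle = 2.0 * math.pi * (h - 1) / n_helices
        center = np.array([R * math.cos(angle), R * math.sin(angle), 0.0])
        up = h % 2 == 1
        for o in range(offset_start, top + 1):
            i = o - offset_start
            z = (i if up else residues_per_helix - 1 - i) * _HELIX_RISE
            phi = _HELIX_TWIST * i
            pos = center + np.array(
                [_HELIX_RADIUS * math.cos(phi), _HELIX_RADIUS * math.sin(phi), z]
            )
            ca[100 * h + o] = pos + rng.normal(0.0, jitter, size=3)

    atoms = [
        AtomRecord("A", res, "ALA", "CA", "C", tuple(coords))
        for res, coords in sorted(ca.items())
    ]

    planted_keys: set[tuple[int, int]] = set()
    pseudo_names = ("CB", "CG", "CD", "CE", "CZ")
    n_pseudo: dict[int, int] = {}

    def _pseudo(res: int, coords: np.ndarray) -> AtomRecord:
        name = pseudo_names[n_pseudo.get(res, 0)]
        n_pseudo[res] = n_pseudo.get(res, 0) + 1
        return AtomRecord("A", res, "ALA", name, "C", tuple(coords))

    for la, lb in planted_contacts:
        ra = segmap.label_to_position(la)
        rb = segmap.label_to_position(lb)
        pa, pb = ca[ra], ca[rb]
        d = float(np.linalg.norm(pb - pa))
        excursion = (d - contact_gap) / 2.0
        if excursion > 8.0 or max(n_pseudo.get(ra, 0), n_pseudo.get(rb, 0)) >= len(
            pseudo_names
        ):
            raise ValueError(
                f"geometric infeasibility: cannot plant pair {la}-{lb} ({d:.1f} A apart)"
            )
        u = (pb - pa) / d
        if excursion > 0:
            atoms.append(_pseudo(ra, pa + u * excursion))
            atoms.append(_pseudo(rb, pb - u * excursion))
        planted_keys.add(tuple(sorted((ra, rb))))

    atoms.sort(key=lambda a: (a.chain, a.res_index, a.atom_name))
    model = StructureModel(structure_id, atoms, segmap)

    # feasibility audit: non-planted inter-helix pairs must stay clear
    residues = model.residues()
    keys = sorted(residues)
    coords = {k: np.array([a.coords for a in residues[k]]) for k in keys}
    for i, ki in enumerate(keys):
        for kj in keys[i + 1 :]:
            pair = tuple(sorted((ki[1], kj[1])))
            if pair in planted_keys:
                continue
            if ki[1] // 100 == kj[1] // 100:  # same helix: separation filter handles
                continue
            dmin = np.min(
                np.linalg.norm(
                    coords[ki][:, None, :] - coords[kj][None, :, :], axis=-1
                )
            )
            if dmin <= cutoff + clearance:
                raise ValueError(
                    f"geometric infeasibility: non-planted pair {ki}-{kj} at "
                    f"{dmin:.2f} A (needs > {cutoff + clearance:.2f} A)"
                )
    return model


# -------------------------------------------------------------- trajectories

def gen_trajectories(
    conditions: dict[str, tuple[int, float, float]] | None = None,
    n_frames: int = 1000,
    seed: int = 0,
    ar1: float = 0.0,
    res_a: str = "3.50",
    res_b: str = "6.34",
) -> pd.DataFrame:
    """Replicate distance time series with a planted between-condition shift.

    ``conditions`` maps condition name -> (n_replicates, mean A, sd A); the
    default is the wild-type-vs-mutant design of the activation-distance
    comparison: 3 replicates around 9 A versus 4 replicates around 12 A,
    sd 1 A.  Frames are i.i.d. Normal(mean, sd) truncated at 0; ``ar1``
    introduces lag-1 autocorrelation (real MD distance series are
    autocorrelated; default 0 keeps frames independent).

    Returns a tidy table (replicate_id, condition, frame, res_a, res_b,
    distance_A).
    """
    conditions = conditions or {"WT": (3, 9.0, 1.0), "MUT": (4, 12.0, 1.0)}
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.0 <= ar1 < 1.0:
        raise ValueError(f"ar1 must be in [0, 1), got {ar1}")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, (n_reps, mean, sd) in conditions.items():
        if sd <= 0:
            raise ValueError(f"sd must be > 0 for condition {cond}")
        for rep in range(1, n_reps + 1):
            eps = rng.normal(0.0, sd, size=n_frames)
            if ar1 > 0:
                values = np.empty(n_frames)
                values[0] = mean + eps[0]
                innov_sd = math.sqrt(1.0 - ar1**2)
                for t in range(1, n_frames):
                    values[t] = mean + ar1 * (values[t - 1] - mean) + innov_sd * eps[t]
            else:
                values = mean + eps
            # truncate at zero by redrawing (distances are positive)
            bad = values <= 0
            while bad.any():
                values[bad] = mean + rng.normal(0.0, sd, size=int(bad.sum()))
                bad = values <= 0
            rid = f"{cond}_rep{rep}"
            rows.append(
                pd.DataFrame(
                    {
                        "replicate_id": rid,
                        "condition": cond,
                        "frame": np.arange(n_frames),
                        "res_a": res_a,
                        "res_b": res_b,
                        "distance_A": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def series_from_table(df: pd.DataFrame):
    """Convert a tidy distance table into DistanceSeries objects."""
    from .trajectory import DistanceSeries

    out = []
    for rid, grp in df.groupby("replicate_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            DistanceSeries(
                replicate_id=str(rid),
                condition=str(grp["condition"].iloc[0]),
                res_a=str(grp["res_a"].iloc[0]) if "res_a" in grp else "",
                res_b=str(grp["res_b"].iloc[0]) if "res_b" in grp else "",
                atom_rule="table",
                values=grp["distance_A"].to_numpy(),
            )
        )
    return out


# ------------------------------------------------------------- dose response

def gen_dose_response(
    model: str = "fourPL",
    params: dict[str, float] | None = None,
    n_doses: int = 8,
    n_replicates: int = 1,
    noise_sd: float = 0.05,
    dose_range: tuple[float, float] = (1e-11, 1e-5),
    seed: int = 0,
    condition: str = "WT",
) -> tuple[pd.DataFrame, dict]:
    """Noisy concentration-response measurements from a known curve.

    Doses are log-spaced over ``dose_range``; responses are the model curve
    plus Gaussian noise of sd ``noise_sd`` (response units; the default
    0.05 is 5% of the default unit top).  Default parameters are a unit
    agonist curve: bottom 0, top 1, logEC50 -8, hill 1.

    Returns (table, ground_truth) with table columns condition, dose,
    replicate, response.
    """
    from .pharm import MODELS, dose_response_model

    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    defaults = {
        "threePL": {"bottom": 0.0, "top": 1.0, "logEC50": -8.0},
        "fourPL": {"bottom": 0.0, "top": 1.0, "logEC50": -8.0, "hill": 1.0},
        "bell": {
            "bottom": 0.0,
            "rise": 1.0,
            "fall": 1.0,
            "log_mid_rise": -9.0,
            "log_mid_fall": -6.0,
        },
    }
    params = {**defaults[model], **(params or {})}
    rng = np.random.default_rng(seed)
    doses = np.logspace(
        math.log10(dose_range[0]), math.log10(dose_range[1]), n_doses
    )
    rows = []
    for rep in range(1, n_replicates + 1):
        clean = dose_response_model(model, doses, params)
        noisy = clean + rng.normal(0.0, noise_sd, size=n_doses) if noise_sd > 0 else clean
        rows.append(
            pd.DataFrame(
                {
                    "condition": condition,
                    "dose": doses,
                    "replicate": rep,
                    "response": noisy,
                }
            )
        )
    truth = {"model": model, "seed": seed, "noise_sd": noise_sd, **params}
    return pd.concat(rows, ignore_index=True), truth
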