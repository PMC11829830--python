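"""Structure-based in/out-of-distribution rank metric.

A fast, model-free score for whether a geometry lies inside the
configurational region covered by a training set. All R = n(n−1)/2
interatomic distances are classified as "bonded" (distance below 1.2× the
mean of the two van der Waals radii) or "non-bonded"; the training set
pools the distances of each class into two distributions, whose 5% and
95% quantiles bound the in-distribution band. A test distance contributes
χ = 1 (bonded, in band), 0.5 (non-bonded, in band) or 0 (out of band),
and the rank of a structure is the sum over all pairs: high rank means
most degrees of freedom are covered by the training data.

A per-pair variant (one distribution per atom pair instead of two pooled
ones) is available via ``per_pair=True`` in :func:`build_rank_profile`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import Dataset, Structure
from .constants import VDW_RADII


@dataclasses.dataclass
class DistancePairTable:
    """Fixed lexicographic atom-pair ordering for one composition."""

    pairs: np.ndarray            # (R, 2), i < j
    atomic_numbers: np.ndarray

    @classmethod
    def for_composition(cls, atomic_numbers) -> "DistancePairTable":
        z = np.asarray(atomic_numbers, dtype=int)
        n = len(z)
        pairs = np.array(
            [(i, j) for i in range(n) for j in range(i + 1, n)], dtype=int
        )
        return cls(pairs=pairs, atomic_numbers=z)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def element_pairs(self):
        return [
            (int(self.atomic_numbers[i]), int(self.atomic_numbers[j]))
            for i, j in self.pairs
        ]


def pairwise_distances(structure_or_coords, table: DistancePairTable):
    """Euclidean distances in the table's fixed pair order."""
    coords = (
        structure_or_coords.coordinates
        if isinstance(structure_or_coords, Structure)
        else np.asarray(structure_or_coords, dtype=float)
    )
    if len(coords) != len(table.atomic_numbers):
        raise ValueError("composition mismatch with the pair table")
    rij = coords[table.pairs[:, 0]] - coords[table.pairs[:, 1]]
    return np.sqrt(np.sum(rij * rij, axis=1))


def bonded_threshold(element_pair, vdw_radii=None) -> float:
    """1.2 × mean of the two van der Waals radii (Å)."""
    radii = vdw_radii or VDW_RADII
    za, zb = element_pair
    try:
        return 1.2 * 0.5 * (radii[za] + radii[zb])
    except KeyError as err:
        raise KeyError(
            f"no van der Waals radius for element Z={err.args[0]}; extend "
            "the radii table via the vdw_radii argument"
        ) from err


def classify_bonded(distance: float, element_pair, vdw_radii=None) -> bool:
    """True iff the distance is strictly below the bonded threshold."""
    return distance < bonded_threshold(element_pair, vdw_radii)


@dataclasses.dataclass
class RankProfile:
    """Training-distribution quantile bands for the rank metric.

    Pooled variant: one (Q5, Q95) band per class. Per-pair variant: one
    band per atom pair and class membership fixed per pair is NOT assumed —
    classification stays per-distance via the vdW rule.
    """

    table: DistancePairTable
    vdw_radii: dict
    q_bond: tuple            # (Q5, Q95) of the pooled bonded distances
    q_nonbond: tuple
    pool_sizes: dict         # {"bonded": int, "nonbonded": int}
    per_pair: bool = False
    q_pairs: np.ndarray | None = None  # (R, 2, 2): [pair, class, quantile]
    degenerate: bool = False

    def band(self, pair_index: int, bonded: bool) -> tuple:
        if self.per_pair:
            q = self.q_pairs[pair_index, 0 if bonded else 1]
            return float(q[0]), float(q[1])
        return self.q_bond if bonded else self.q_nonbond

    # -- persistence ------------------------------------------------------
    def save(self, path):
        payload = {
            "atomic_numbers": self.table.atomic_numbers.tolist(),
            "vdw_radii": {str(k): v for k, v in self.vdw_radii.items()},
            "q_bond": list(self.q_bond),
            "q_nonbond": list(self.q_nonbond),
            "pool_sizes": self.pool_sizes,
            "per_pair": bool(self.per_pair),
            "q_pairs": None
            if self.q_pairs is None
            else self.q_pairs.tolist(),
            "degenerate": bool(self.degenerate),
            "bonded_rule": "r < 1.2 * mean(vdw radii)",
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "RankProfile":
        p = json.loads(Path(path).read_text())
        return cls(
            table=DistancePairTable.for_composition(p["atomic_numbers"]),
            vdw_radii={int(k): v for k, v in p["vdw_radii"].items()},
            q_bond=tuple(p["q_bond"]),
            q_nonbond=tuple(p["q_nonbond"]),
            pool_sizes=p["pool_sizes"],
            per_pair=p["per_pair"],
            q_pairs=None if p["q_pairs"] is None else np.array(p["q_pairs"]),
            degenerate=p["degenerate"],
        )


class EmptyPoolError(ValueError):
    pass


def build_rank_profile(
    training: Dataset,
    vdw_radii: dict | None = None,
    per_pair: bool = False,
    quantiles=(0.05, 0.95),
) -> RankProfile:
    """Pool every training distance into bonded/non-bonded distributions.

    Quantiles use linear interpolation. A degenerate profile (Q5 == Q95,
    e.g. from a single structure) is flagged, not rejected.
    """
    if len(training) == 0:
        raise EmptyPoolError("empty training set")
    radii = vdw_radii or VDW_RADII
    table = DistancePairTable.for_composition(training.atomic_numbers)
    thresholds = np.array(
        [bonded_threshold(ep, radii) for ep in table.element_pairs()]
    )
    dist = np.array(
        [pairwise_distances(s, table) for s in training]
    )  # (n_structures, R)
    bonded_mask = dist < thresholds[None, :]
    pool_b = dist[bonded_mask]
    pool_nb = dist[~bonded_mask]
    if len(pool_b) == 0 or len(pool_nb) == 0:
        raise EmptyPoolError(
            "one distance class is empty over the whole training set"
        )
    q_bond = tuple(np.quantile(pool_b, quantiles))
    q_nonbond = tuple(np.quantile(pool_nb, quantiles))
    q_pairs = None
    if per_pair:
        q_pairs = np.zeros((table.n_pairs, 2, 2))
        for p in range(table.n_pairs):
            for ci, mask in enumerate((bonded_mask[:, p], ~bonded_mask[:, p])):
                vals = dist[mask, p]
                if len(vals):
                    q_pairs[p, ci] = np.quantile(vals, quantiles)
                else:
                    q_pairs[p, ci] = (np.inf, -np.inf)  # empty: never in band
    degenerate = q_bond[0] == q_bond[1] or q_nonbond[0] == q_nonbond[1]
    return RankProfile(
        table=table,
        vdw_radii=dict(radii),
        q_bond=q_bond,
        q_nonbond=q_nonbond,
        pool_sizes={
            "bonded": int(len(pool_b)),
            "nonbonded": int(len(pool_nb)),
        },
        per_pair=per_pair,
        q_pairs=q_pairs,
        degenerate=degenerate,
    )


def chi(
    distance: float,
    element_pair,
    profile: RankProfile,
    pair_index: int = 0,
) -> float:
    """Contribution of one distance: 1 / 0.5 (in band) or 0 (out of band)."""
    bonded = classify_bonded(distance, element_pair, profile.vdw_radii)
    lo, hi = profile.band(pair_index, bonded)
    if lo < distance < hi:
        return 1.0 if bonded else 0.5
    return 0.0


@dataclasses.dataclass
class RankResult:
    rank: float
    rank_bonded: float
    rank_nonbonded: float
    chi_values: np.ndarray

    def __post_init__(self):
        assert np.isclose(self.rank, self.rank_bonded + self.rank_nonbonded)


def rank(structure_or_coords, profile: RankProfile) -> RankResult:
    """Total rank of a structure: Σ_i χ(r_i) over all pairs."""
    table = profile.table
    dist = pairwise_distances(structure_or_coords, table)
    thresholds = np.array(
        [
            bonded_threshold(ep, profile.vdw_radii)
            for ep in table.element_pairs()
        ]
    )
    bonded = dist < thresholds
    chis = np.zeros(len(dist))
    rank_b = rank_nb = 0.0
    for p, (d, is_b) in enumerate(zip(dist, bonded)):
        lo, hi = profile.band(p, bool(is_b))
        if lo < d < hi:
            chis[p] = 1.0 if is_b else 0.5
            if is_b:
                rank_b += 1.0
            else:
                rank_nb += 0.5
    return RankResult(
        rank=rank_b + rank_nb,
        rank_bonded=rank_b,
        rank_nonbonded=rank_nb,
        chi_values=chis,
    )


def rank_reports(
    squared_error: np.ndarray,
    uncertainty: np.ndarray,
    rank_results: list,
    energies: np.ndarray | None = None,
    bin_width: float = 0.5,
) -> dict:
    """Per-rank MSE/MV tables and the bonded × non-bonded occupancy map.

    Ranks are binned in ``bin_width`` steps (0.5 resolves the half-integer
    contributions of non-bonded pairs). Returns DataFrames: ``by_rank``
    (rank bin, MSE, MV, count) and ``map2d`` (rank_bonded, rank_nonbonded,
    count, occupancy %, mean energy).
    """
    se = np.asarray(squared_error, dtype=float)
    mv = np.asarray(uncertainty, dtype=float)
    ranks = np.array([r.rank for r in rank_results])
    rb = np.array([r.rank_bonded for r in rank_results])
    rnb = np.array([r.rank_nonbonded for r in rank_results])
    if not (len(se) == len(mv) == len(ranks)):
        raise ValueError("input lengths differ")

    def snap(v):
        return np.round(v / bin_width) * bin_width

    frame = pd.DataFrame(
        {"rank": snap(ranks), "mse": se, "mv": mv}
    )
    by_rank = (
        frame.groupby("rank")
        .agg(mse=("mse", "mean"), mv=("mv", "mean"), count=("mse", "size"))
        .reset_index()
    )
    map_frame = pd.DataFrame(
        {
            "rank_bonded": snap(rb),
            "rank_nonbonded": snap(rnb),
            "energy": (
                np.asarray(energies, dtype=float)
                if energies is not None
                else np.full(len(ranks), np.nan)
            ),
        }
    )
    map2d = (
        map_frame.groupby(["rank_bonded", "rank_nonbonded"])
        .agg(count=("energy", "size"), mean_energy=("energy", "mean"))
        .reset_index()
    )
    map2d["occupancy_pct"] = 100.0 * map2d["count"] / len(ranks)
    return {"by_rank": by_rank, "map2d": map2d}
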