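"""Molecular dataset containers and I/O.

Internal units are fixed: Å for coordinates, kcal/mol for energies,
kcal/mol/Å for forces, Debye for dipoles. Unit conversion (for extended-XYZ
files written in the eV dialect) happens at the I/O boundary only.

The on-disk interchange format is extended XYZ: a per-frame atom count,
a comment line of ``key=value`` pairs (``energy=...``, optionally
``charge=...``, ``dipole="x y z"`` and a ``Properties=`` descriptor), and
one row per atom with the element symbol, Cartesian coordinates and,
optionally, force columns named ``forces``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shlex
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .constants import ATOMIC_NUMBERS, ELEMENT_SYMBOLS, EV_TO_KCAL_PER_MOL

logger = logging.getLogger("pesuq")

SPLITS = ("train", "validation", "test")


class CompositionError(ValueError):
    """Structures in one dataset must share atom count and composition."""


class ExtxyzParseError(ValueError):
    pass


@dataclasses.dataclass
class Structure:
    """A single molecular geometry with optional labels.

    atomic_numbers : (n,) int array
    coordinates    : (n, 3) float array, Å
    energy         : kcal/mol, or None
    forces         : (n, 3) kcal/mol/Å, or None
    total_charge   : elementary charges, or None
    dipole         : (3,) Debye, or None
    tag            : free-text label, e.g. "train" or "ood"
    """

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    energy: float | None = None
    forces: np.ndarray | None = None
    total_charge: float | None = None
    dipole: np.ndarray | None = None
    tag: str = ""

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.atomic_numbers)
        if n < 2:
            raise ValueError("a structure needs at least 2 atoms")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} != ({n}, 3)"
            )
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coordinates.shape:
                raise ValueError("forces and coordinates shapes differ")
            if not np.all(np.isfinite(self.forces)):
                raise ValueError("non-finite forces")
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError("non-finite energy")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def symbols(self) -> list[str]:
        return [ELEMENT_SYMBOLS[z] for z in self.atomic_numbers]


class Dataset:
    """An ordered, index-addressable collection of same-composition structures.

    The index is the identity of a structure: every evaluation module refers
    to structures by their position here. ``split_labels`` partitions the
    collection into train / validation / test.
    """

    def __init__(self, structures: Sequence[Structure], split_labels=None):
        self.structures = list(structures)
        if self.structures:
            ref = self.structures[0].atomic_numbers
            for k, s in enumerate(self.structures):
                if not np.array_equal(s.atomic_numbers, ref):
                    raise CompositionError(
                        f"structure {k} has a different composition"
                    )
        if split_labels is None:
            split_labels = ["train"] * len(self.structures)
        self.split_labels = list(split_labels)
        if len(self.split_labels) != len(self.structures):
            raise ValueError("one split label per structure required")
        for lab in self.split_labels:
            if lab not in SPLITS:
                raise ValueError(f"unknown split label {lab!r}")

    def __len__(self) -> int:
        return len(self.structures)

    def __getitem__(self, i) -> Structure:
        return self.structures[i]

    def __iter__(self):
        return iter(self.structures)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return self.structures[0].atomic_numbers

    def indices(self, split: str) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.split_labels) if lab == split],
            dtype=int,
        )

    def subset(self, indices: Iterable[int]) -> "Dataset":
        idx = list(indices)
        return Dataset(
            [self.structures[i] for i in idx],
            [self.split_labels[i] for i in idx],
        )

    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.structures], dtype=float)


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _parse_comment(line: str) -> dict:
    fields = {}
    for token in shlex.split(line):
        if "=" not in token:
            continue
        key, val = token.split("=", 1)
        fields[key.lower()] = val
    return fields


def read_extxyz(path, energy_unit: str = "kcal/mol") -> Dataset:
    """Read an extended-XYZ trajectory into a Dataset.

    Every frame must carry an ``energy=`` field in its comment line; force
    columns are optional. ``energy_unit`` may be ``"kcal/mol"`` (default) or
    ``"eV"`` — in the latter case energies and forces are converted to the
    internal kcal/mol units on the way in.
    """
    scale = {"kcal/mol": 1.0, "eV": EV_TO_KCAL_PER_MOL}[energy_unit]
    lines = Path(path).read_text().splitlines()
    structures = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as err:
            raise ExtxyzParseError(
                f"frame {frame}: malformed atom-count line {lines[pos]!r}"
            ) from err
        if pos + 1 + n >= len(lines) + 1 and pos + 1 + n > len(lines):
            raise ExtxyzParseError(f"frame {frame}: truncated frame")
        fields = _parse_comment(lines[pos + 1])
        if "energy" not in fields:
            raise ExtxyzParseError(f"frame {frame}: missing energy field")
        energy = float(fields["energy"]) * scale
        charge = float(fields["charge"]) if "charge" in fields else None
        dipole = None
        if "dipole" in fields:
            dipole = np.array([float(v) for v in fields["dipole"].split()])
        znums, coords, forces = [], [], []
        has_forces = None
        for row in lines[pos + 2 : pos + 2 + n]:
            parts = row.split()
            if len(parts) not in (4, 7):
                raise ExtxyzParseError(
                    f"frame {frame}: bad atom row {row!r}"
                )
            sym = parts[0]
            if sym not in ATOMIC_NUMBERS:
                raise ExtxyzParseError(
                    f"frame {frame}: unknown element {sym!r}"
                )
            znums.append(ATOMIC_NUMBERS[sym])
            coords.append([float(v) for v in parts[1:4]])
            row_has_forces = len(parts) == 7
            if has_forces is None:
                has_forces = row_has_forces
            elif has_forces != row_has_forces:
                raise ExtxyzParseError(
                    f"frame {frame}: inconsistent force columns"
                )
            if row_has_forces:
                forces.append([float(v) for v in parts[4:7]])
        structures.append(
            Structure(
                atomic_numbers=np.array(znums),
                coordinates=np.array(coords),
                energy=energy,
                forces=np.array(forces) * scale if has_forces else None,
                total_charge=charge,
                dipole=dipole,
                tag=fields.get("tag", ""),
            )
        )
        pos += 2 + n
        frame += 1
    try:
        return Dataset(structures)
    except CompositionError as err:
        raise CompositionError(f"{path}: {err}") from err


def write_extxyz(dataset: Dataset, path) -> None:
    """Write a Dataset as extended XYZ (energies always, forces if present)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    out = []
    for s in dataset:
        props = "species:S:1:pos:R:3"
        if s.forces is not None:
            props += ":forces:R:3"
        comment = f'Properties={props} energy={s.energy!r}'
        if s.total_charge is not None:
            comment += f" charge={s.total_charge!r}"
        if s.dipole is not None:
            comment += ' dipole="{:.17g} {:.17g} {:.17g}"'.format(*s.dipole)
        if s.tag:
            comment += f" tag={s.tag}"
        out.append(str(s.n_atoms))
        out.append(comment)
        for sym, xyz, frc in zip(
            s.symbols(),
            s.coordinates,
            s.forces if s.forces is not None else [None] * s.n_atoms,
        ):
            row = f"{sym} {xyz[0]:.17g} {xyz[1]:.17g} {xyz[2]:.17g}"
            if frc is not None:
                row += f" {frc[0]:.17g} {frc[1]:.17g} {frc[2]:.17g}"
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# array bundle (fast binary reload of a full dataset)
# ---------------------------------------------------------------------------

def save_bundle(dataset: Dataset, path) -> None:
    """Persist a Dataset as a compressed array bundle (.npz)."""
    n = len(dataset)
    arrays = {
        "Z": dataset.atomic_numbers,
        "R": np.stack([s.coordinates for s in dataset]),
        "E": dataset.energies(),
        "split": np.array(dataset.split_labels),
        "tag": np.array([s.tag for s in dataset]),
    }
    if all(s.forces is not None for s in dataset):
        arrays["F"] = np.stack([s.forces for s in dataset])
    if all(s.total_charge is not None for s in dataset):
        arrays["Q"] = np.array([s.total_charge for s in dataset])
    if all(s.dipole is not None for s in dataset):
        arrays["D"] = np.stack([s.dipole for s in dataset])
    np.savez_compressed(path, **arrays)
    logger.info("wrote bundle %s with %d structures", path, n)


def load_bundle(path) -> Dataset:
    with np.load(path, allow_pickle=False) as data:
        n = data["R"].shape[0]
        structures = [
            Structure(
                atomic_numbers=data["Z"],
                coordinates=data["R"][i],
                energy=float(data["E"][i]),
                forces=data["F"][i] if "F" in data else None,
                total_charge=float(data["Q"][i]) if "Q" in data else None,
                dipole=data["D"][i] if "D" in data else None,
                tag=str(data["tag"][i]) if "tag" in data else "",
            )
            for i in range(n)
        ]
        labels = [str(x) for x in data["split"]]
    return Dataset(structures, labels)


# ---------------------------------------------------------------------------
# splits, config, seeding
# ---------------------------------------------------------------------------

def split_dataset(dataset: Dataset, train_fraction: float, seed: int) -> Dataset:
    """Assign train/validation labels by a seeded random permutation.

    ``floor(n * train_fraction)`` structures become "train", the rest
    "validation". Structures already labelled "test" keep their label.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    pool = [i for i, lab in enumerate(dataset.split_labels) if lab != "test"]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    n_train = int(np.floor(len(pool) * train_fraction))
    labels = list(dataset.split_labels)
    for rank_pos, p in enumerate(perm):
        labels[pool[p]] = "train" if rank_pos < n_train else "validation"
    return Dataset(dataset.structures, labels)


@dataclasses.dataclass
class RunConfig:
    """Top-level run configuration: one master seed plus per-module blocks."""

    seed: int = 0
    paths: dict = dataclasses.field(default_factory=dict)
    sections: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            paths=dict(raw.get("paths", {})),
            sections={
                k: v for k, v in raw.items() if k not in ("seed", "paths")
            },
        )

    def derive_seed(self, stream: str) -> int:
        """A deterministic per-purpose child seed (< 2**31)."""
        h = np.uint64(14695981039346656037)
        for ch in f"{self.seed}:{stream}".encode():
            h = np.uint64((int(h) ^ ch) * 1099511628211 % 2**64)
        return int(h % np.uint64(2**31 - 1))


def setup_logging(logfile=None, seed: int | None = None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
    if seed is not None:
        logger.info("master seed = %d", seed)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
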