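"""Multi-frame XYZ trajectory reading, subsampling and writing.

The XYZ dialect accepted here is the ubiquitous one produced by MD
post-processing tools: per frame an atom-count line, a free-form comment
line, then one ``<symbol> <x> <y> <z>`` line per atom, whitespace
delimited, coordinates in Å. Frames are 0-indexed everywhere, including
error messages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Frame", "Trajectory", "read_xyz_trajectory", "write_xyz"]

# Symbols of the 118 recognized chemical elements.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe
    Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn
    Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W
    Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf
    Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


class XYZFormatError(ValueError):
    """Raised when a trajectory file violates the XYZ format."""


@dataclass(frozen=True)
class Frame:
    """One molecular snapshot: element symbols plus Cartesian coordinates (Å)."""

    elements: tuple[str, ...]
    coordinates: np.ndarray  # shape (n_atoms, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must have shape (n, 3), got {coords.shape}")
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coordinates", coords)
        if len(self.elements) != len(coords):
            raise ValueError(
                f"{len(self.elements)} element symbols but {len(coords)} coordinate rows"
            )
        for symbol in self.elements:
            if symbol not in ELEMENT_SYMBOLS:
                raise ValueError(f"unrecognized chemical element symbol {symbol!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance(self, i: int, j: int) -> float:
        """Pairwise distance r_ij in Å."""
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))

    def angle(self, j: int, i: int, k: int) -> float:
        """Inner angle θ_jik at vertex ``i`` (radians, in [0, π])."""
        u = self.coordinates[j] - self.coordinates[i]
        v = self.coordinates[k] - self.coordinates[i]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(cos, -1.0, 1.0)))


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of frames sharing a single topology."""

    frames: tuple[Frame, ...]
    source_path: str = "<memory>"
    stride_applied: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        if not self.frames:
            raise ValueError("a trajectory must contain at least one frame")
        if self.stride_applied < 1:
            raise ValueError("stride_applied must be a positive integer")
        reference = self.frames[0].elements
        for idx, frame in enumerate(self.frames):
            if frame.elements != reference:
                raise ValueError(
                    f"inconsistent topology: frame {idx} has elements "
                    f"{frame.elements}, expected {reference}"
                )

    @property
    def elements(self) -> tuple[str, ...]:
        return self.frames[0].elements

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


def _parse_frame(lines: list[str], start: int, frame_index: int) -> tuple[Frame, int]:
    header = lines[start].split()
    try:
        n_atoms = int(header[0])
    except (IndexError, ValueError) as exc:
        raise XYZFormatError(
            f"frame {frame_index}: expected an atom-count line, got {lines[start]!r}"
        ) from exc
    if n_atoms < 1:
        raise XYZFormatError(f"frame {frame_index}: non-positive atom count {n_atoms}")
    end = start + 2 + n_atoms
    if end > len(lines):
        raise XYZFormatError(
            f"frame {frame_index}: declares {n_atoms} atoms but the file ends early"
        )
    elements: list[str] = []
    coords = np.empty((n_atoms, 3), dtype=float)
    for row, line in enumerate(lines[start + 2 : end]):
        parts = line.split()
        if len(parts) < 4:
            raise XYZFormatError(
                f"frame {frame_index}: atom line {row} has "
                f"{len(parts)} fields, expected at least 4: {line!r}"
            )
        elements.append(parts[0])
        try:
            coords[row] = [float(parts[1]), float(parts[2]), float(parts[3])]
        except ValueError as exc:
            raise XYZFormatError(
                f"frame {frame_index}: unparsable coordinate on atom line {row}: {line!r}"
            ) from exc
    try:
        frame = Frame(tuple(elements), coords)
    except ValueError as exc:
        raise XYZFormatError(f"frame {frame_index}: {exc}") from exc
    return frame, end


def read_xyz_trajectory(path: str | Path, stride: int = 1) -> Trajectory:
    """Read a multi-frame XYZ file, keeping every ``stride``-th frame.

    Frame 0 is always kept, so the returned trajectory holds
    ``ceil(total / stride)`` frames. All frames are parsed and validated
    (atom counts, coordinates, single topology) even when skipped by the
    stride, so a malformed frame anywhere in the file is reported.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    cursor = 0
    index = 0
    while cursor < len(lines):
        if not lines[cursor].strip():  # trailing blank lines
            cursor += 1
            continue
        frame, cursor = _parse_frame(lines, cursor, index)
        frames.append(frame)
        index += 1
    if not frames:
        raise XYZFormatError(f"no frames found in {path}")
    return Trajectory(
        frames=tuple(frames[::stride]), source_path=str(path), stride_applied=stride
    )


def write_xyz(
    frames: Iterable[Frame] | Trajectory,
    path: str | Path,
    comment: str = "",
    precision: int = 10,
) -> None:
    """Write frames as standard multi-frame XYZ (Å, ``precision`` decimals)."""
    frame_list: Sequence[Frame] = list(frames)
    if not frame_list:
        raise ValueError("cannot write an empty frame list")
    path = Path(path)
    fmt = f"{{sym}} {{x:.{precision}f}} {{y:.{precision}f}} {{z:.{precision}f}}"
    chunks: list[str] = []
    for frame in frame_list:
        chunks.append(str(frame.n_atoms))
        chunks.append(comment)
        for sym, (x, y, z) in zip(frame.elements, frame.coordinates):
            chunks.append(fmt.format(sym=sym, x=x, y=y, z=z))
    path.write_text("\n".join(chunks) + "\n")


def subsampled_length(total: int, stride: int) -> int:
    """Frame count after keeping every ``stride``-th frame starting at 0."""
    return math.ceil(total / stride)
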