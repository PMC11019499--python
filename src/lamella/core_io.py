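"""Shared domain types and file I/O.

Coordinates are nanometres everywhere; scattering vectors are nm^-1.
Coarse-grained configurations use GRO-style fixed columns (1-based ids in
files, 0-based indexing in memory); 1-D SAXS profiles are plain ASCII
columns with ``#`` comments.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "ParseError",
    "ValidationError",
    "CGTopology",
    "CGFrame",
    "SAXSProfile",
    "PeakSettings",
    "StructureFactorSettings",
    "LeafletSettings",
    "RunConfig",
    "read_cg_frame",
    "read_cg_frames",
    "write_cg_frame",
    "read_saxs_profile",
    "write_saxs_profile",
    "ethanol_volume_fraction",
    "solvent_counts_for_fraction",
]

#: Molar volumes used for the bead-count <-> vol% conversion (cm^3 mol^-1).
WATER_MOLAR_VOLUME = 18.07
ETHANOL_MOLAR_VOLUME = 58.5

#: Bulk water number density (molecules nm^-3), used when filling solvent gaps.
WATER_NUMBER_DENSITY = 33.4


class ParseError(ValueError):
    """A file did not parse as the expected fixed-column / columnar format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

_HEAD = ("NC", "PH", "GL")
_PALMITOYL = ("EST", "CM", "CM", "CM", "CT2")
_OLEOYL = ("EST", "CM", "CM", "CMD2", "CM", "CT2")


@dataclass(frozen=True)
class CGTopology:
    """Per-lipid bead ordering and solvent mapping for the CG POPC model.

    The lipid is headgroup (choline NC, phosphate PH, glycerol GL) followed
    by the palmitoyl chain and the oleoyl chain, each running from its ester
    anchor (EST) to the terminal CT2 bead.  The oleoyl chain carries exactly
    one CMD2 bead (segment 4 from EST) marking the cis double bond.  One WAT
    bead maps to three water molecules; one ETNL bead to one ethanol.
    """

    head_beads: tuple[str, ...] = _HEAD
    palmitoyl: tuple[str, ...] = _PALMITOYL
    oleoyl: tuple[str, ...] = _OLEOYL
    water_bead: str = "WAT"
    ethanol_bead: str = "ETNL"
    waters_per_bead: int = 3
    water_molar_volume: float = WATER_MOLAR_VOLUME
    ethanol_molar_volume: float = ETHANOL_MOLAR_VOLUME

    def __post_init__(self) -> None:
        for name, chain in (("palmitoyl", self.palmitoyl), ("oleoyl", self.oleoyl)):
            if len(chain) < 2 or chain[0] != "EST" or chain[-1] != "CT2":
                raise ValidationError(
                    f"{name} chain must start at EST and end at CT2, got {chain}"
                )
        if self.oleoyl.count("CMD2") != 1:
            raise ValidationError("oleoyl chain must contain exactly one CMD2 bead")
        if self.waters_per_bead < 1:
            raise ValidationError("waters_per_bead must be >= 1")

    @property
    def lipid_beads(self) -> tuple[str, ...]:
        return self.head_beads + self.palmitoyl + self.oleoyl

    @property
    def beads_per_lipid(self) -> int:
        return len(self.lipid_beads)

    @property
    def palmitoyl_indices(self) -> tuple[int, ...]:
        start = len(self.head_beads)
        return tuple(range(start, start + len(self.palmitoyl)))

    @property
    def oleoyl_indices(self) -> tuple[int, ...]:
        start = len(self.head_beads) + len(self.palmitoyl)
        return tuple(range(start, start + len(self.oleoyl)))

    @property
    def ph_index(self) -> int:
        return self.head_beads.index("PH")

    @property
    def known_beads(self) -> frozenset[str]:
        return frozenset(self.lipid_beads) | {self.water_bead, self.ethanol_bead}


# ---------------------------------------------------------------------------
# CG frame
# ---------------------------------------------------------------------------


@dataclass
class CGFrame:
    """One snapshot of a stacked lamellar system.

    ``positions`` is (n_beads, 3) in nm in an orthorhombic box with the
    stacking normal along z.  ``mol_ids`` group beads into molecules;
    ``resnames`` are POPC / WAT / ETNL per bead.
    """

    positions: np.ndarray
    bead_names: np.ndarray
    mol_ids: np.ndarray
    resnames: np.ndarray
    box: np.ndarray
    n_bilayers: int | None = None
    topology: CGTopology = field(default_factory=CGTopology)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must have shape (n, 3)")
        n = len(self.positions)
        if not (len(self.bead_names) == len(self.mol_ids) == len(self.resnames) == n):
            raise ValidationError("per-bead arrays must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite coordinates")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValidationError(f"box lengths must be positive, got {self.box}")
        n_popc_beads = int(np.sum(self.resnames == "POPC"))
        bpl = self.topology.beads_per_lipid
        if n_popc_beads % bpl:
            raise ValidationError(
                f"{n_popc_beads} POPC beads is not a multiple of {bpl} beads/lipid"
            )
        if self.n_bilayers is not None and self.n_lipids % (2 * self.n_bilayers):
            raise ValidationError(
                f"{self.n_lipids} lipids cannot split into two leaflets "
                f"x {self.n_bilayers} bilayers"
            )

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def popc_mask(self) -> np.ndarray:
        return self.resnames == "POPC"

    @property
    def n_lipids(self) -> int:
        return int(np.sum(self.popc_mask)) // self.topology.beads_per_lipid

    def lipid_mol_ids(self) -> np.ndarray:
        """Sorted unique molecule ids of the POPC lipids."""
        return np.unique(self.mol_ids[self.popc_mask])

    def lipid_positions(self) -> np.ndarray:
        """POPC coordinates as (n_lipids, beads_per_lipid, 3), bead order as
        in the topology, lipid order by ascending molecule id."""
        mask = self.popc_mask
        ids = self.mol_ids[mask]
        order = np.argsort(ids, kind="stable")
        pos = self.positions[mask][order]
        names = self.bead_names[mask][order]
        bpl = self.topology.beads_per_lipid
        nlip = self.n_lipids
        if len(pos) != nlip * bpl:
            raise ValidationError("inconsistent POPC bead bookkeeping")
        seq = np.asarray(self.topology.lipid_beads, dtype=object)
        names = names.reshape(nlip, bpl)
        if not np.all(names == seq[None, :]):
            bad = int(np.argmax(np.any(names != seq[None, :], axis=1)))
            raise ValidationError(
                f"lipid {bad} bead sequence {tuple(names[bad])} does not match "
                f"topology {tuple(seq)}"
            )
        return pos.reshape(nlip, bpl, 3)


# ---------------------------------------------------------------------------
# GRO-style fixed-column I/O
# ---------------------------------------------------------------------------


def write_cg_frame(
    frame: CGFrame, path: str | Path, title: str = "CG lamellar frame", append: bool = False
) -> None:
    """Write one frame in GRO fixed columns (multi-frame = concatenation)."""
    path = Path(path)
    lines = [title, f"{frame.n_beads:5d}"]
    for i in range(frame.n_beads):
        resid = int(frame.mol_ids[i]) % 100000
        x, y, z = frame.positions[i]
        lines.append(
            f"{resid:5d}{str(frame.resnames[i]):<5s}{str(frame.bead_names[i]):>5s}"
            f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    lines.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    mode = "a" if append else "w"
    with path.open(mode) as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_atom_line(line: str, lineno: int) -> tuple[int, str, str, float, float, float]:
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        beadname = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed fixed-column record: {line!r}") from exc
    return resid, resname, beadname, x, y, z


def iter_cg_frames(
    path: str | Path,
    topology: CGTopology | None = None,
    n_bilayers: int | None = None,
) -> Iterator[CGFrame]:
    """Iterate frames of a (possibly concatenated multi-frame) GRO-style file."""
    topology = topology or CGTopology()
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        if i + 1 >= len(lines):
            raise ParseError(f"line {i + 1}: truncated frame header")
        try:
            natoms = int(lines[i + 1])
        except ValueError as exc:
            raise ParseError(f"line {i + 2}: expected atom count, got {lines[i + 1]!r}") from exc
        first_atom = i + 2
        box_line_idx = first_atom + natoms
        if box_line_idx >= len(lines):
            raise ParseError(f"line {len(lines)}: truncated frame (missing box line)")
        mol_ids, resnames, bead_names, xyz = [], [], [], []
        for j in range(natoms):
            resid, resname, bead, x, y, z = _parse_atom_line(
                lines[first_atom + j], first_atom + j + 1
            )
            if bead not in topology.known_beads:
                raise ValidationError(
                    f"line {first_atom + j + 1}: unknown bead type {bead!r}"
                )
            mol_ids.append(resid)
            resnames.append(resname)
            bead_names.append(bead)
            xyz.append((x, y, z))
        box_tokens = lines[box_line_idx].split()
        if len(box_tokens) < 3:
            raise ParseError(f"line {box_line_idx + 1}: box line needs 3 numbers")
        try:
            box = [float(t) for t in box_tokens[:3]]
        except ValueError as exc:
            raise ParseError(f"line {box_line_idx + 1}: malformed box line") from exc
        yield CGFrame(
            positions=np.array(xyz),
            bead_names=np.array(bead_names, dtype=object),
            mol_ids=np.array(mol_ids),
            resnames=np.array(resnames, dtype=object),
            box=np.array(box),
            n_bilayers=n_bilayers,
            topology=topology,
        )
        i = box_line_idx + 1


def read_cg_frame(
    path: str | Path, topology: CGTopology | None = None, n_bilayers: int | None = None
) -> CGFrame:
    """Read the first frame of a GRO-style configuration file."""
    try:
        return next(iter_cg_frames(path, topology, n_bilayers))
    except StopIteration:  # pragma: no cover - empty file
        raise ParseError(f"{path}: no frames found") from None


def read_cg_frames(
    path: str | Path, topology: CGTopology | None = None, n_bilayers: int | None = None
) -> list[CGFrame]:
    """Read all concatenated frames of a GRO-style file."""
    return list(iter_cg_frames(path, topology, n_bilayers))


# ---------------------------------------------------------------------------
# SAXS profiles
# ---------------------------------------------------------------------------


@dataclass
class SAXSProfile:
    """A 1-D scattering profile: q (nm^-1, strictly increasing), I(q) >= 0,
    optional per-point uncertainty and the contact time (s) it was taken at."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    contact_time: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.q):
                raise ValidationError("sigma length mismatch")
        if len(self.q) != len(self.intensity):
            raise ValidationError("q / intensity length mismatch")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValidationError("intensity must be finite and non-negative")

    @property
    def n_points(self) -> int:
        return len(self.q)


_TIME_RE = re.compile(r"\bt\s*=\s*([-+]?\d+(?:\.\d*)?(?:[eE][-+]?\d+)?)")


def read_saxs_profile(path: str | Path, clamp_negative: bool = True) -> SAXSProfile:
    """Read an ASCII profile (columns q I [sigma]; '#' comments).

    Duplicate q rows are merged by averaging.  Negative intensities are
    clamped to zero with a warning (or rejected if ``clamp_negative`` is
    False).  A header comment like ``# t = 12.6 s`` sets the contact time.
    """
    path = Path(path)
    contact_time: float | None = None
    rows: list[tuple[float, ...]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                m = _TIME_RE.search(stripped)
                if m:
                    contact_time = float(m.group(1))
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ParseError(f"line {lineno}: expected >= 2 columns")
            try:
                rows.append(tuple(float(t) for t in tokens[:3]))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric value") from exc
    if len(rows) < 3:
        raise ParseError(f"{path}: fewer than 3 data rows")
    has_sigma = all(len(r) == 3 for r in rows)
    arr = np.array([r[: 3 if has_sigma else 2] for r in rows])
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    q, inverse = np.unique(arr[:, 0], return_inverse=True)
    intensity = np.bincount(inverse, weights=arr[:, 1]) / np.bincount(inverse)
    sigma = None
    if has_sigma:
        sigma = np.bincount(inverse, weights=arr[:, 2]) / np.bincount(inverse)
    if np.any(intensity < 0):
        if not clamp_negative:
            raise ValidationError(f"{path}: negative intensity")
        warnings.warn(f"{path}: negative intensities clamped to 0", stacklevel=2)
        intensity = np.clip(intensity, 0.0, None)
    return SAXSProfile(q=q, intensity=intensity, sigma=sigma, contact_time=contact_time)


def write_saxs_profile(profile: SAXSProfile, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if profile.contact_time is not None:
            fh.write(f"# t = {profile.contact_time:g} s\n")
        fh.write("# q[nm^-1] I[a.u.]" + (" sigma" if profile.sigma is not None else "") + "\n")
        for i in range(profile.n_points):
            row = f"{profile.q[i]:.6e} {profile.intensity[i]:.6e}"
            if profile.sigma is not None:
                row += f" {profile.sigma[i]:.6e}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# ethanol bookkeeping
# ---------------------------------------------------------------------------


def ethanol_volume_fraction(
    n_etnl: int, n_wat: int, topology: CGTopology | None = None
) -> float:
    """Ethanol volume percent of a WAT/ETNL solvent bead mixture.

    One ETNL bead is one ethanol molecule; one WAT bead is three waters.
    """
    if n_etnl < 0 or n_wat < 0:
        raise ValidationError("bead counts must be non-negative")
    if n_etnl == 0 and n_wat == 0:
        raise ValidationError("undefined composition: no solvent beads")
    topology = topology or CGTopology()
    v_eth = n_etnl * topology.ethanol_molar_volume
    v_wat = topology.waters_per_bead * n_wat * topology.water_molar_volume
    return 100.0 * v_eth / (v_eth + v_wat)


def solvent_counts_for_fraction(
    vol_pct: float, total_beads: int, topology: CGTopology | None = None
) -> tuple[int, int]:
    """Inverse of :func:`ethanol_volume_fraction` at fixed total bead count.

    Returns integer ``(n_etnl, n_wat)`` whose forward fraction matches
    ``vol_pct`` up to bead-count rounding.
    """
    if not 0.0 <= vol_pct <= 100.0:
        raise ValidationError("vol_pct must be in [0, 100]")
    if total_beads < 1:
        raise ValidationError("need at least one solvent bead")
    topology = topology or CGTopology()
    f = vol_pct / 100.0
    v_e = topology.ethanol_molar_volume
    v_w = topology.waters_per_bead * topology.water_molar_volume
    if f == 1.0:
        return total_beads, 0
    n_e = f * v_w * total_beads / (v_e * (1.0 - f) + f * v_w)
    n_etnl = int(round(n_e))
    return n_etnl, total_beads - n_etnl


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class PeakSettings:
    """Bragg peak detection knobs (see saxs_bragg)."""

    smoothing_window: int = 5
    prominence_factor: float = 5.0      # x noise sd of the background residual
    min_rel_prominence: float = 0.005   # x local background level
    order_tolerance: float = 0.15       # relative tolerance for order assignment
    refine_halfwidth: float = 0.12      # nm^-1, Gaussian refinement window

    def validate(self) -> None:
        if self.smoothing_window < 1:
            raise ValidationError("smoothing_window must be >= 1")
        for name in ("prominence_factor", "min_rel_prominence", "order_tolerance", "refine_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class StructureFactorSettings:
    q_max: float = 4.0
    polarization: float = 1.0
    # per-bead-type scattering factors; anything absent defaults to 1
    scattering_factors: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.q_max <= 0 or self.polarization <= 0:
            raise ValidationError("q_max and polarization must be > 0")


@dataclass
class LeafletSettings:
    min_plane_gap: float = 0.5  # nm, smallest credible separation of PH planes
    persistence: int = 2        # frames a new leaflet label must persist

    def validate(self) -> None:
        if self.min_plane_gap <= 0 or self.persistence < 1:
            raise ValidationError("leaflet settings must be positive")


@dataclass
class RunConfig:
    """Whole-pipeline configuration; every CLI flag has a twin here."""

    peaks: PeakSettings = field(default_factory=PeakSettings)
    structure_factor: StructureFactorSettings = field(default_factory=StructureFactorSettings)
    leaflets: LeafletSettings = field(default_factory=LeafletSettings)
    mixing: dict = field(default_factory=dict)  # ChannelSpec kwargs (see lamella.mixing)
    seed: int = 0

    def validate(self) -> None:
        self.peaks.validate()
        self.structure_factor.validate()
        self.leaflets.validate()
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "peaks": vars(self.peaks).copy(),
            "structure_factor": vars(self.structure_factor).copy(),
            "leaflets": vars(self.leaflets).copy(),
            "mixing": dict(self.mixing),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            peaks=PeakSettings(**payload.get("peaks", {})),
            structure_factor=StructureFactorSettings(**payload.get("structure_factor", {})),
            leaflets=LeafletSettings(**payload.get("leaflets", {})),
            mixing=payload.get("mixing", {}) or {},
            seed=int(payload.get("seed", 0)),
        )
        cfg.validate()
        return cfg
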