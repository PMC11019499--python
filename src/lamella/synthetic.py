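"""Synthetic lamellar configurations and SAXS profiles with planted parameters.

Every analysis stage in this package is exercised against fixtures from this
module: stacked CG POPC bilayers built segment-by-segment with a known area
per lipid, phosphate-phosphate thickness, repeat distance, chain order,
ethanol partitioning and (optionally) planted flip-flopped lipids; and 1-D
lamellar scattering profiles made of Gaussian Bragg orders on a power-law
background with Poisson-like counting noise.

The geometry is fabricated, not simulated: there is no force field, no
excluded volume, and no dynamics.  What is guaranteed is that the planted
observables (A, d_PP, d, S, flip-flop count, ethanol partition) are the
ground truth the trajectory metrics must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import (
    CGFrame,
    CGTopology,
    SAXSProfile,
    ValidationError,
    WATER_NUMBER_DENSITY,
    solvent_counts_for_fraction,
)

__all__ = [
    "LamellarSpec",
    "SAXSProfileSpec",
    "generate_lamellar_config",
    "generate_lamellar_trajectory",
    "planted_flip_mol_ids",
    "generate_saxs_profile",
    "generate_time_series",
]

# head-group stack offsets from the phosphate plane, along the outward normal (nm)
_NC_OFFSET = 0.25
_GL_OFFSET = -0.20
_EST_OFFSET = -0.45
_EST_LATERAL = 0.15   # the two ester anchors sit side by side
_BOND_LENGTH = 0.42   # nm between consecutive chain segments: tails span the leaflet
_HEAD_CLEARANCE = 0.0  # hydration water reaches the phosphate planes


@dataclass
class LamellarSpec:
    """Planted parameters of a stacked-bilayer configuration.

    Defaults reproduce the water-only reference system: three POPC bilayers
    at a 6.1 nm repeat, area per lipid 0.647 nm^2 and d_PP 3.85 nm.
    """

    n_bilayers: int = 3
    lipids_per_leaflet: int = 100
    area_per_lipid: float = 0.647   # nm^2
    d_pp: float = 3.85              # nm, phosphate-phosphate thickness
    d_spacing: float = 6.1          # nm, lamellar repeat
    order_target: float = 0.35      # planted segmental order parameter
    ethanol_vol_pct: float = 0.0
    membrane_partition: float = 0.3  # fraction of ETNL beads inside membrane cores
    n_flipflops: int = 0
    jitter: float = 0.05            # nm positional noise on lipid anchors
    chain_inward_bias: bool = True  # disordered bond component drawn from the inward hemisphere
    seed: int = 0
    topology: CGTopology = field(default_factory=CGTopology)

    def __post_init__(self) -> None:
        if not self.d_spacing > self.d_pp > 0:
            raise ValidationError("need d_spacing > d_pp > 0")
        if self.area_per_lipid <= 0:
            raise ValidationError("area_per_lipid must be > 0")
        if not -0.5 <= self.order_target <= 1.0:
            raise ValidationError("order_target must lie in [-0.5, 1]")
        if not 0 <= self.ethanol_vol_pct <= 100:
            raise ValidationError("ethanol_vol_pct must be in [0, 100]")
        if not 0 <= self.membrane_partition <= 1:
            raise ValidationError("membrane_partition must be in [0, 1]")
        if self.n_bilayers < 1 or self.lipids_per_leaflet < 1:
            raise ValidationError("need at least one bilayer and one lipid per leaflet")
        if not 0 <= self.n_flipflops <= self.n_lipids:
            raise ValidationError("flip-flop count must be within [0, lipid count]")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")

    @property
    def n_lipids(self) -> int:
        return 2 * self.n_bilayers * self.lipids_per_leaflet

    @property
    def box(self) -> np.ndarray:
        side = np.sqrt(self.lipids_per_leaflet * self.area_per_lipid)
        return np.array([side, side, self.n_bilayers * self.d_spacing])


def planted_flip_mol_ids(spec: LamellarSpec) -> list[int]:
    """Molecule ids of the lipids planted head-across-the-midplane.

    Flips are taken from the lower leaflets round-robin over bilayers, so a
    3-bilayer spec with n_flipflops=2 flips one lipid in each of two
    bilayers (the situation reported for the highest ethanol content).
    """
    npl = spec.lipids_per_leaflet
    ids = []
    for j in range(spec.n_flipflops):
        bilayer = j % spec.n_bilayers
        index = j // spec.n_bilayers
        ids.append(1 + bilayer * 2 * npl + index)
    return ids


def _sample_bond_dirs(
    n: int,
    s_target: float,
    inward: float,
    rng: np.random.Generator,
    inward_bias: bool = True,
) -> np.ndarray:
    """Unit bond vectors whose segmental order parameter is s_target in
    expectation.

    Mixture model: with probability p a bond is exactly along the inward
    normal (order 1) for s_target >= 0, or exactly in-plane (order -1/2)
    for s_target < 0; otherwise the direction is random with cos uniform —
    over the inward hemisphere when ``inward_bias`` (so chains progress
    toward the midplane like real tails and the membrane core fills up), or
    over the full sphere otherwise.  Either way the random component has
    order 0, since the cos^2 distribution is the same.
    """
    dirs = np.empty((n, 3))
    # order-0 random component
    u = rng.uniform(0.0, 1.0, n) * inward if inward_bias else rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    r = np.sqrt(1.0 - u * u)
    dirs[:, 0] = r * np.cos(phi)
    dirs[:, 1] = r * np.sin(phi)
    dirs[:, 2] = u
    if s_target >= 0:
        p = s_target
        pick = rng.random(n) < p
        dirs[pick] = np.array([0.0, 0.0, inward])
    else:
        p = -2.0 * s_target
        pick = rng.random(n) < p
        n_pick = int(pick.sum())
        phi2 = rng.uniform(0.0, 2 * np.pi, n_pick)
        dirs[pick] = np.stack(
            [np.cos(phi2), np.sin(phi2), np.zeros(n_pick)], axis=1
        )
    return dirs


def _build_lipid(
    anchor: np.ndarray,
    outward: float,
    spec: LamellarSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bead coordinates of one lipid whose PH bead sits at ``anchor`` and
    whose head points along ``outward`` (+1/-1 z)."""
    top = spec.topology
    beads = np.empty((top.beads_per_lipid, 3))
    # head: NC, PH, GL stacked along the outward normal
    beads[0] = anchor + [0.0, 0.0, outward * _NC_OFFSET]
    beads[1] = anchor
    beads[2] = anchor + [0.0, 0.0, outward * _GL_OFFSET]
    inward = -outward
    for chain_idx, (indices, lateral) in enumerate(
        ((top.palmitoyl_indices, +_EST_LATERAL), (top.oleoyl_indices, -_EST_LATERAL))
    ):
        est = anchor + [lateral, 0.0, outward * _EST_OFFSET]
        beads[indices[0]] = est
        n_bonds = len(indices) - 1
        bonds = _sample_bond_dirs(
            n_bonds, spec.order_target, inward, rng, inward_bias=spec.chain_inward_bias
        )
        pos = est.copy()
        for b, idx in enumerate(indices[1:]):
            pos = pos + _BOND_LENGTH * bonds[b]
            beads[idx] = pos
    return beads


def _solvent_slabs(spec: LamellarSpec) -> list[tuple[float, float]]:
    """(z_lo, z_hi) of the solvent gaps between head-group zones."""
    half = spec.d_pp / 2 + _HEAD_CLEARANCE
    slabs = []
    for i in range(spec.n_bilayers):
        mid = (i + 0.5) * spec.d_spacing
        lo = mid + half
        hi = mid + spec.d_spacing - half
        if hi <= lo:
            raise ValidationError(
                "no solvent gap: d_spacing too close to d_pp + head clearance"
            )
        slabs.append((lo, hi))
    return slabs


def generate_lamellar_config(
    spec: LamellarSpec,
    rng: np.random.Generator | None = None,
    flips_active: bool = True,
) -> CGFrame:
    """Build one frame of the stacked lamellar system.

    Bilayer midplanes sit at (i + 1/2) * d; PH planes at +-d_PP/2 around
    each midplane; Lz = n_bilayers * d and Lx * Ly = lipids_per_leaflet * A,
    so molecular_area and d_pp recover the planted values by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    top = spec.topology
    box = spec.box
    lx, ly, lz = box
    npl = spec.lipids_per_leaflet
    flip_ids = set(planted_flip_mol_ids(spec)) if flips_active else set()

    # jittered square lattice of lipid anchors, shared by all leaflets
    m = int(np.ceil(np.sqrt(npl)))
    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    lattice = np.stack([(gx.ravel() + 0.5) * lx / m, (gy.ravel() + 0.5) * ly / m], axis=1)[:npl]

    positions, bead_names, mol_ids, resnames = [], [], [], []
    mol_id = 1
    for b in range(spec.n_bilayers):
        mid = (b + 0.5) * spec.d_spacing
        for leaflet_sign in (-1.0, +1.0):  # lower then upper
            for x0, y0 in lattice:
                sign = leaflet_sign
                if mol_id in flip_ids:
                    sign = -sign  # planted flip: head across the midplane
                anchor = np.array([x0, y0, mid + sign * spec.d_pp / 2])
                anchor += rng.normal(0.0, spec.jitter, 3) if spec.jitter > 0 else 0.0
                beads = _build_lipid(anchor, outward=sign, spec=spec, rng=rng)
                positions.append(beads)
                bead_names.extend(top.lipid_beads)
                mol_ids.extend([mol_id] * top.beads_per_lipid)
                resnames.extend(["POPC"] * top.beads_per_lipid)
                mol_id += 1

    # solvent: fill the inter-bilayer gaps at bulk-water bead density
    slabs = _solvent_slabs(spec)
    gap_volume = lx * ly * sum(hi - lo for lo, hi in slabs)
    total_beads = max(1, int(round(gap_volume * WATER_NUMBER_DENSITY / top.waters_per_bead)))
    n_etnl, n_wat = solvent_counts_for_fraction(spec.ethanol_vol_pct, total_beads, top)
    n_mem = int(round(spec.membrane_partition * n_etnl))
    n_solv_etnl = n_etnl - n_mem

    def _place_in_slabs(n: int) -> np.ndarray:
        widths = np.array([hi - lo for lo, hi in slabs])
        choice = rng.choice(len(slabs), size=n, p=widths / widths.sum())
        z = np.array([rng.uniform(*slabs[c]) for c in choice])
        xy = rng.uniform(0.0, [lx, ly], size=(n, 2))
        return np.column_stack([xy, z])

    solvent_pos, solvent_names, solvent_res = [], [], []
    if n_wat:
        solvent_pos.append(_place_in_slabs(n_wat))
        solvent_names += [top.water_bead] * n_wat
        solvent_res += ["WAT"] * n_wat
    if n_solv_etnl:
        solvent_pos.append(_place_in_slabs(n_solv_etnl))
        solvent_names += [top.ethanol_bead] * n_solv_etnl
        solvent_res += ["ETNL"] * n_solv_etnl
    if n_mem:
        which = rng.integers(0, spec.n_bilayers, n_mem)
        mids = (which + 0.5) * spec.d_spacing
        z = mids + rng.uniform(-spec.d_pp / 2, spec.d_pp / 2, n_mem)
        xy = rng.uniform(0.0, [lx, ly], size=(n_mem, 2))
        solvent_pos.append(np.column_stack([xy, z]))
        solvent_names += [top.ethanol_bead] * n_mem
        solvent_res += ["ETNL"] * n_mem

    all_pos = np.concatenate([np.concatenate(positions)] + solvent_pos) if solvent_pos else np.concatenate(positions)
    n_solvent = len(all_pos) - len(mol_ids)
    mol_ids = np.array(mol_ids + list(range(mol_id, mol_id + n_solvent)))
    bead_names = np.array(bead_names + solvent_names, dtype=object)
    resnames = np.array(resnames + solvent_res, dtype=object)

    # wrap into the primary box
    all_pos = all_pos - np.floor(all_pos / box) * box

    return CGFrame(
        positions=all_pos,
        bead_names=bead_names,
        mol_ids=mol_ids,
        resnames=resnames,
        box=box,
        n_bilayers=spec.n_bilayers,
        topology=top,
    )


def generate_lamellar_trajectory(
    spec: LamellarSpec, n_frames: int, flip_frame: int | None = None
) -> list[CGFrame]:
    """Multi-frame trajectory with independent jitter/orientation noise per
    frame.  Planted flip-flops switch leaflet at ``flip_frame`` (they are
    flipped in every frame when ``flip_frame`` is None)."""
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).spawn(n_frames)
    frames = []
    for f in range(n_frames):
        active = True if flip_frame is None else f >= flip_frame
        frames.append(
            generate_lamellar_config(
                spec, rng=np.random.default_rng(seeds[f]), flips_active=active
            )
        )
    return frames


# ---------------------------------------------------------------------------
# SAXS profiles
# ---------------------------------------------------------------------------


@dataclass
class SAXSProfileSpec:
    """Planted parameters of a lamellar scattering profile.

    Bragg orders are Gaussians at q_n = 2*pi*n/d (or at explicit
    ``peak_centers``) over an a*q^-b + c background; noise is Poisson
    counting noise at a counts-per-intensity scale set by ``noise``
    (0 disables noise).
    """

    d_spacing: float = 6.1
    n_orders: int = 3
    amplitudes: tuple[float, ...] = (30.0, 8.0, 3.0)
    peak_width: float = 0.03            # nm^-1 Gaussian sigma
    background: tuple[float, float, float] = (10.0, 2.0, 0.5)  # a, b, c
    noise: float = 0.05                 # intensity units per count; 0 = noiseless
    q_min: float = 0.1
    q_max: float = 4.0
    n_points: int = 1000
    peak_centers: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_spacing <= 0:
            raise ValidationError("d_spacing must be > 0")
        if self.n_orders < 0:
            raise ValidationError("n_orders must be >= 0")
        if self.peak_width <= 0:
            raise ValidationError("peak_width must be > 0")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")
        if self.q_min <= 0 or self.q_max <= self.q_min or self.n_points < 10:
            raise ValidationError("invalid q grid")
        centers = self.centers
        if centers and not (self.q_min <= centers[0] <= self.q_max):
            raise ValidationError(
                f"q grid [{self.q_min}, {self.q_max}] does not cover the first "
                f"order at {centers[0]:.3f} nm^-1"
            )

    @property
    def centers(self) -> tuple[float, ...]:
        if self.peak_centers is not None:
            return tuple(self.peak_centers)
        return tuple(2 * np.pi * n / self.d_spacing for n in range(1, self.n_orders + 1))


def generate_saxs_profile(
    spec: SAXSProfileSpec, contact_time: float | None = None
) -> SAXSProfile:
    """Render the profile on its q grid; identical spec + seed is bit-identical."""
    q = np.linspace(spec.q_min, spec.q_max, spec.n_points)
    a, b, c = spec.background
    intensity = a * np.power(q, -b) + c
    centers = spec.centers
    amps = spec.amplitudes
    if centers and len(amps) < len(centers):
        raise ValidationError("need one amplitude per visible order")
    for center, amp in zip(centers, amps):
        intensity = intensity + amp * np.exp(-((q - center) ** 2) / (2 * spec.peak_width**2))
    sigma = None
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(intensity / spec.noise)
        intensity = counts * spec.noise
        sigma = np.sqrt(np.maximum(counts, 1)) * spec.noise
    return SAXSProfile(q=q, intensity=intensity, sigma=sigma, contact_time=contact_time)


def generate_time_series(
    schedule: Sequence[tuple[float, float | None, tuple[float, ...] | None]],
    spec: SAXSProfileSpec | None = None,
) -> list[SAXSProfile]:
    """One profile per (contact time, d, amplitudes) entry.

    ``d`` None marks a peak-free (unilamellar) time point; amplitudes None
    keeps the base spec's.  Entries must be strictly increasing in time.
    Per-entry seeds derive from the base seed, so the series is reproducible
    yet each profile carries independent noise.
    """
    if len(schedule) == 0:
        raise ValidationError("empty schedule")
    times = [entry[0] for entry in schedule]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("schedule times must be strictly increasing")
    base = spec or SAXSProfileSpec()
    seeds = np.random.SeedSequence(base.seed).spawn(len(schedule))
    profiles = []
    for i, (t, d, amps) in enumerate(schedule):
        seed_i = int(seeds[i].generate_state(1)[0] % (2**31))
        if d is None:
            entry = replace(base, n_orders=0, amplitudes=(), peak_centers=None, seed=seed_i)
        else:
            amps = tuple(amps) if amps is not None else base.amplitudes
            entry = replace(
                base,
                d_spacing=d,
                n_orders=len(amps),
                amplitudes=amps,
                peak_centers=None,
                seed=seed_i,
            )
        profiles.append(generate_saxs_profile(entry, contact_time=t))
    return profiles
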