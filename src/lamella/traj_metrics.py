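"""Trajectory-derived observables of stacked CG bilayers.

Implements the quantities a lamellar membrane study reads off a
coarse-grained trajectory: the structure factor along the stacking normal
(F(q) = sum_k f_k exp(i q z_k), I = |F|^2 P with f_k = 1 by default),
number-density profiles, area per lipid, phosphate-phosphate thickness
d_PP, segmental order parameters S = <(3 cos^2 v - 1)/2> of the tail bonds,
chain-vector angle distributions, leaflet assignment by 1-D clustering of
phosphate planes, flip-flop detection, and ethanol penetration into the
membrane core.

All z arithmetic uses the minimum-image convention in the orthorhombic box;
beads are wrapped into the primary box before histogramming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import (
    CGFrame,
    CGTopology,
    LeafletSettings,
    StructureFactorSettings,
    ValidationError,
)

__all__ = [
    "StructureFactorResult",
    "DensityProfile",
    "BilayerMetrics",
    "OrderProfile",
    "ChainAngleDistribution",
    "LeafletRecord",
    "FlipFlopEvent",
    "structure_factor",
    "harmonic_q_grid",
    "density_profile",
    "molecular_area",
    "molecular_area_trajectory",
    "assign_leaflets",
    "d_pp",
    "segmental_order",
    "chain_angle_distribution",
    "detect_flipflops",
    "ethanol_penetration",
    "bilayer_metrics",
]


def _min_image(dz: np.ndarray | float, length: float):
    return dz - length * np.round(np.asarray(dz) / length)


def _wrap(z: np.ndarray, length: float) -> np.ndarray:
    return np.mod(z, length)


def _circular_mean(z: np.ndarray, length: float) -> float:
    theta = 2 * np.pi * z / length
    mean = np.angle(np.mean(np.exp(1j * theta)))
    return float(np.mod(mean * length / (2 * np.pi), length))


# ---------------------------------------------------------------------------
# structure factor
# ---------------------------------------------------------------------------


@dataclass
class StructureFactorResult:
    """Lamellar-normal structure factor: q grid (harmonics of 2*pi/Lz),
    frame-averaged complex amplitude, raw intensity <|F|^2> P and its
    per-bead^2 normalisation."""

    q: np.ndarray
    amplitude: np.ndarray          # frame-averaged F(q)
    intensity: np.ndarray          # <|F(q)|^2> * P
    intensity_normalized: np.ndarray
    polarization: float
    n_beads: int


def harmonic_q_grid(lz: float, q_max: float) -> np.ndarray:
    """q values compatible with the periodic box: m * 2*pi/Lz, m = 0..m_max."""
    dq = 2 * np.pi / lz
    m_max = int(np.floor(q_max / dq + 1e-9))
    return dq * np.arange(m_max + 1)


def structure_factor(
    frames: Sequence[CGFrame],
    q: np.ndarray | None = None,
    settings: StructureFactorSettings | None = None,
) -> StructureFactorResult:
    """F(q) = sum_k f_k exp(i q z_k) along the stacking normal, with the
    intensity averaged over frames as <|F|^2> * P.

    The q grid is restricted to multiples of 2*pi/Lz; anything else is
    incompatible with the periodic images and rejected.
    """
    if len(frames) == 0:
        raise ValidationError("need at least one frame")
    s = settings or StructureFactorSettings()
    lz = float(frames[0].box[2])
    for fr in frames:
        if abs(float(fr.box[2]) - lz) > 1e-9:
            raise ValidationError("frames must share the box length along z")
    dq = 2 * np.pi / lz
    if q is None:
        q = harmonic_q_grid(lz, s.q_max)
    else:
        q = np.asarray(q, dtype=float)
        m = q / dq
        if np.any(np.abs(m - np.round(m)) > 1e-6):
            raise ValidationError(
                f"q must be multiples of 2*pi/Lz = {dq:.6f} nm^-1 "
                f"(harmonics m * {dq:.6f})"
            )
    amp = np.zeros(len(q), dtype=complex)
    inten = np.zeros(len(q))
    n_beads = frames[0].n_beads
    for fr in frames:
        z = fr.positions[:, 2]
        f_k = np.ones(fr.n_beads)
        if s.scattering_factors:
            for bead, val in s.scattering_factors.items():
                f_k[fr.bead_names == bead] = val
        phases = np.exp(1j * np.outer(z, q))  # (n_beads, n_q)
        F = f_k @ phases
        amp += F
        inten += np.abs(F) ** 2
    amp /= len(frames)
    inten = inten / len(frames) * s.polarization
    return StructureFactorResult(
        q=q,
        amplitude=amp,
        intensity=inten,
        intensity_normalized=inten / n_beads**2,
        polarization=s.polarization,
        n_beads=n_beads,
    )


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Frame-averaged number densities (nm^-3) along z, one array per
    selection key (bead type or residue name, optionally split ':upper' /
    ':lower' by leaflet)."""

    z: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float
    box_area: float
    n_frames: int

    def counts(self, key: str) -> float:
        """Mean bead count per frame implied by the profile (integral check)."""
        return float(np.sum(self.densities[key]) * self.bin_width * self.box_area)


def density_profile(
    frames: Sequence[CGFrame],
    selection: Sequence[str],
    n_bins: int = 100,
    split_leaflets: bool = False,
    leaflets: Sequence["LeafletRecord"] | None = None,
) -> DensityProfile:
    """Histogram the selected bead types / residue names along z.

    With ``split_leaflets`` lipid beads are attributed to their lipid's
    current leaflet label (requires one LeafletRecord per frame).
    """
    if len(selection) == 0:
        raise ValidationError("empty selection")
    if n_bins < 10:
        raise ValidationError("need at least 10 bins")
    if split_leaflets and (leaflets is None or len(leaflets) != len(frames)):
        raise ValidationError("split_leaflets requires one LeafletRecord per frame")
    box = frames[0].box
    lz = float(box[2])
    edges = np.linspace(0.0, lz, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_volume = (lz / n_bins) * box[0] * box[1]
    keys: list[str] = []
    for sel in selection:
        if split_leaflets:
            keys += [f"{sel}:upper", f"{sel}:lower"]
        else:
            keys.append(sel)
    hists = {k: np.zeros(n_bins) for k in keys}
    for fi, fr in enumerate(frames):
        z = _wrap(fr.positions[:, 2], lz)
        for sel in selection:
            mask = (fr.bead_names == sel) | (fr.resnames == sel)
            if split_leaflets:
                rec = leaflets[fi]
                label_of = dict(zip(rec.mol_ids.tolist(), rec.leaflet.tolist()))
                sel_ids = fr.mol_ids[mask]
                lab = np.array([label_of.get(int(m), "") for m in sel_ids])
                for side in ("upper", "lower"):
                    hists[f"{sel}:{side}"] += np.histogram(
                        z[mask][lab == side], bins=edges
                    )[0]
            else:
                hists[sel] += np.histogram(z[mask], bins=edges)[0]
    densities = {k: h / (len(frames) * bin_volume) for k, h in hists.items()}
    return DensityProfile(
        z=centers,
        densities=densities,
        bin_width=lz / n_bins,
        box_area=float(box[0] * box[1]),
        n_frames=len(frames),
    )


# ---------------------------------------------------------------------------
# area per lipid
# ---------------------------------------------------------------------------


def molecular_area(frame: CGFrame, n_bilayers: int | None = None) -> float:
    """Area per lipid: Lx*Ly / lipids_per_leaflet."""
    n_b = n_bilayers if n_bilayers is not None else frame.n_bilayers
    if n_b is None:
        raise ValidationError("number of bilayers unknown")
    n_lip = frame.n_lipids
    if n_lip == 0:
        raise ValidationError("frame contains no lipids")
    per_leaflet = n_lip / (2 * n_b)
    return float(frame.box[0] * frame.box[1] / per_leaflet)


def molecular_area_trajectory(
    frames: Sequence[CGFrame], n_bilayers: int | None = None
) -> tuple[float, float]:
    """Trajectory mean and frame-to-frame sd of the area per lipid."""
    areas = np.array([molecular_area(fr, n_bilayers) for fr in frames])
    return float(areas.mean()), float(areas.std(ddof=0))


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------


@dataclass
class LeafletRecord:
    """Per-lipid leaflet labels for one frame, plus the fitted phosphate
    plane and midplane positions."""

    mol_ids: np.ndarray            # lipid molecule ids
    bilayer: np.ndarray            # bilayer index per lipid
    leaflet: np.ndarray            # 'upper' | 'lower' per lipid
    plane_z: dict                  # (bilayer, leaflet) -> mean PH z (nm)
    midplanes: np.ndarray          # bilayer midplane z (nm)
    lz: float

    def label(self, mol_id: int) -> tuple[int, str]:
        i = int(np.searchsorted(self.mol_ids, mol_id))
        if i >= len(self.mol_ids) or self.mol_ids[i] != mol_id:
            raise KeyError(f"no lipid with molecule id {mol_id}")
        return int(self.bilayer[i]), str(self.leaflet[i])


def assign_leaflets(
    frame: CGFrame,
    n_bilayers: int | None = None,
    settings: LeafletSettings | None = None,
) -> LeafletRecord:
    """Assign every lipid to a (bilayer, leaflet) by its phosphate bead.

    Phosphate z coordinates are clustered into 2*n_bilayers planes by
    cutting the circular (periodic) sorted sequence at its largest gaps;
    planes are paired into bilayers using the tail direction of their
    lipids (tails point toward the bilayer midplane).  Suitable for flat
    lamellae only — a vesicle has no global normal for this to work with.
    """
    s = settings or LeafletSettings()
    n_b = n_bilayers if n_bilayers is not None else frame.n_bilayers
    if n_b is None:
        raise ValidationError("number of bilayers unknown")
    top = frame.topology
    lip = frame.lipid_positions()
    mol_ids = frame.lipid_mol_ids()
    lz = float(frame.box[2])
    ph_z = _wrap(lip[:, top.ph_index, 2], lz)
    ct2 = [top.palmitoyl_indices[-1], top.oleoyl_indices[-1]]
    tail_rel = np.mean(
        [_min_image(lip[:, i, 2] - lip[:, top.ph_index, 2], lz) for i in ct2], axis=0
    )
    n_planes = 2 * n_b
    if len(ph_z) < n_planes:
        raise ValidationError("fewer lipids than leaflets")

    order = np.argsort(ph_z)
    zs = ph_z[order]
    gaps = np.diff(np.append(zs, zs[0] + lz))  # circular gaps
    boundary = np.sort(np.argsort(gaps)[-n_planes:])  # cluster ends
    chosen_gaps = np.sort(gaps[boundary])
    if chosen_gaps[0] < s.min_plane_gap:
        raise ValidationError(
            f"cannot resolve {n_planes} phosphate planes: smallest separating "
            f"gap {chosen_gaps[0]:.3f} nm < {s.min_plane_gap} nm "
            f"(gap spectrum: {np.sort(gaps)[-n_planes - 2:][::-1].round(3)})"
        )
    start = boundary[-1] + 1  # first cluster starts after the last boundary
    idx = np.arange(len(zs))
    shifted = np.mod(idx - start, len(zs))
    # cluster id = number of boundaries passed, walking from `start`
    ends_shifted = np.sort(np.mod(boundary - start, len(zs)))
    cluster_of = np.searchsorted(ends_shifted, shifted, side="left")
    clusters = np.empty(len(ph_z), dtype=int)
    clusters[order] = cluster_of

    means = np.array([_circular_mean(ph_z[clusters == c], lz) for c in range(n_planes)])
    orient = np.array(
        [np.sign(np.mean(tail_rel[clusters == c])) for c in range(n_planes)]
    )
    by_z = np.argsort(means)
    # rotate so the sequence starts on a lower leaflet (tails pointing up)
    starts = [r for r in range(n_planes) if orient[by_z[r]] > 0]
    paired = None
    for r in starts:
        ring = np.roll(by_z, -r)
        if all(orient[ring[2 * i]] > 0 and orient[ring[2 * i + 1]] < 0 for i in range(n_b)):
            paired = ring
            break
    if paired is None:
        raise ValidationError(
            "phosphate planes do not alternate lower/upper as a lamellar stack "
            f"(orientations along z: {orient[by_z]})"
        )

    bilayer_arr = np.empty(len(ph_z), dtype=int)
    leaflet_arr = np.empty(len(ph_z), dtype=object)
    plane_z: dict = {}
    midplanes = np.empty(n_b)
    for b in range(n_b):
        lower_c, upper_c = paired[2 * b], paired[2 * b + 1]
        bilayer_arr[clusters == lower_c] = b
        bilayer_arr[clusters == upper_c] = b
        leaflet_arr[clusters == lower_c] = "lower"
        leaflet_arr[clusters == upper_c] = "upper"
        z_lo, z_up = means[lower_c], means[upper_c]
        plane_z[(b, "lower")] = float(z_lo)
        plane_z[(b, "upper")] = float(z_up)
        midplanes[b] = np.mod(z_lo + 0.5 * np.mod(z_up - z_lo, lz), lz)
    return LeafletRecord(
        mol_ids=mol_ids,
        bilayer=bilayer_arr,
        leaflet=leaflet_arr,
        plane_z=plane_z,
        midplanes=midplanes,
        lz=lz,
    )


# ---------------------------------------------------------------------------
# d_PP
# ---------------------------------------------------------------------------


@dataclass
class BilayerMetrics:
    """Area per lipid and per-bilayer phosphate-phosphate thickness with
    frame-to-frame standard deviations."""

    area: float
    area_sd: float
    d_pp: np.ndarray      # per bilayer, trajectory mean
    d_pp_sd: np.ndarray
    degenerate: np.ndarray  # True where a bilayer collapsed to d_PP ~ 0


def d_pp(
    frames: Sequence[CGFrame],
    leaflets: Sequence[LeafletRecord],
    degenerate_tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bilayer phosphate-phosphate distance along z.

    Returns (mean, sd, degenerate_flag) arrays over bilayers; mean/sd are
    over frames.  A leaflet without phosphate beads is an error; a bilayer
    whose two planes coincide is flagged degenerate rather than rejected.
    """
    if len(frames) != len(leaflets) or len(frames) == 0:
        raise ValidationError("need one LeafletRecord per frame")
    n_b = int(leaflets[0].midplanes.shape[0])
    values = np.empty((len(frames), n_b))
    for fi, (fr, rec) in enumerate(zip(frames, leaflets)):
        top = fr.topology
        lip = fr.lipid_positions()
        lz = float(fr.box[2])
        ph_z = _wrap(lip[:, top.ph_index, 2], lz)
        for b in range(n_b):
            upper = ph_z[(rec.bilayer == b) & (rec.leaflet == "upper")]
            lower = ph_z[(rec.bilayer == b) & (rec.leaflet == "lower")]
            if len(upper) == 0 or len(lower) == 0:
                raise ValidationError(f"bilayer {b}: a leaflet has no phosphate beads")
            z_up = _circular_mean(upper, lz)
            z_lo = _circular_mean(lower, lz)
            values[fi, b] = np.mod(z_up - z_lo, lz)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    return mean, sd, mean < degenerate_tol


def bilayer_metrics(
    frames: Sequence[CGFrame],
    leaflets: Sequence[LeafletRecord] | None = None,
    n_bilayers: int | None = None,
    tail_fraction: float = 1.0,
) -> BilayerMetrics:
    """Area per lipid and d_PP over the last ``tail_fraction`` of the
    trajectory (analysis-window convention for equilibrated tails)."""
    if not 0 < tail_fraction <= 1:
        raise ValidationError("tail_fraction must be in (0, 1]")
    start = len(frames) - max(1, int(round(tail_fraction * len(frames))))
    window = list(frames[start:])
    if leaflets is None:
        leaflets = [assign_leaflets(fr, n_bilayers) for fr in window]
    else:
        leaflets = list(leaflets[start:])
    area, area_sd = molecular_area_trajectory(window, n_bilayers)
    mean, sd, degenerate = d_pp(window, leaflets)
    return BilayerMetrics(
        area=area, area_sd=area_sd, d_pp=mean, d_pp_sd=sd, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# segmental order
# ---------------------------------------------------------------------------


@dataclass
class OrderProfile:
    """Segmental order S_b = <(3 cos^2 v_b - 1)/2> per tail bond, where v is
    the bond angle to the bilayer normal.  Bond 1 connects EST to segment 2;
    numbering runs to the terminal CT2."""

    bond_index: dict[str, np.ndarray]
    order: dict[str, np.ndarray]
    n_samples: int

    def chain(self, name: str) -> np.ndarray:
        return self.order[name]


def segmental_order(
    frames: Sequence[CGFrame], topology: CGTopology | None = None
) -> OrderProfile:
    """Order parameter of every tail bond, for the palmitoyl and oleoyl
    chains separately, averaged over lipids and frames."""
    if len(frames) == 0:
        raise ValidationError("need at least one frame")
    top = topology or frames[0].topology
    chains = {"palmitoyl": top.palmitoyl_indices, "oleoyl": top.oleoyl_indices}
    sums = {name: np.zeros(len(idx) - 1) for name, idx in chains.items()}
    count = 0
    for fr in frames:
        lip = fr.lipid_positions()
        box = fr.box
        count += len(lip)
        for name, idx in chains.items():
            vec = lip[:, idx[1:], :] - lip[:, idx[:-1], :]
            for ax in range(3):
                vec[:, :, ax] = _min_image(vec[:, :, ax], box[ax])
            norms = np.linalg.norm(vec, axis=2)
            if np.any(norms == 0):
                raise ValidationError("zero-length bond vector")
            cos = vec[:, :, 2] / norms
            sums[name] += np.sum(1.5 * cos**2 - 0.5, axis=0)
    order = {name: s / count for name, s in sums.items()}
    bond_index = {name: np.arange(1, len(idx)) for name, idx in chains.items()}
    return OrderProfile(bond_index=bond_index, order=order, n_samples=count)


# ---------------------------------------------------------------------------
# chain-vector angle distribution
# ---------------------------------------------------------------------------


@dataclass
class ChainAngleDistribution:
    """Probability histogram of cos(theta) of the EST->CT2 chain vectors
    (leaflet signs preserved, so an ordered stack peaks at +-1)."""

    bin_edges: np.ndarray
    probability: np.ndarray
    mean_cos: float
    variance: float
    alignment_spread: float  # <(1 - |cos theta|)^2>: 0 = perfectly aligned

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def chain_angle_distribution(
    frames: Sequence[CGFrame],
    topology: CGTopology | None = None,
    n_bins: int = 40,
) -> ChainAngleDistribution:
    if len(frames) == 0:
        raise ValidationError("need at least one frame")
    top = topology or frames[0].topology
    cos_all = []
    for fr in frames:
        lip = fr.lipid_positions()
        if len(lip) == 0:
            raise ValidationError("frame contains no lipids")
        box = fr.box
        for idx in (top.palmitoyl_indices, top.oleoyl_indices):
            vec = lip[:, idx[-1], :] - lip[:, idx[0], :]
            for ax in range(3):
                vec[:, ax] = _min_image(vec[:, ax], box[ax])
            cos_all.append(vec[:, 2] / np.linalg.norm(vec, axis=1))
    cos = np.concatenate(cos_all)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(np.clip(cos, -1, 1), bins=edges)
    prob = hist / hist.sum()
    return ChainAngleDistribution(
        bin_edges=edges,
        probability=prob,
        mean_cos=float(cos.mean()),
        variance=float(cos.var()),
        alignment_spread=float(np.mean((1.0 - np.abs(cos)) ** 2)),
    )


# ---------------------------------------------------------------------------
# flip-flops
# ---------------------------------------------------------------------------


@dataclass
class FlipFlopEvent:
    mol_id: int
    frame: int            # first frame with the new label
    bilayer: int
    from_leaflet: str
    to_leaflet: str


def detect_flipflops(
    leaflets: Sequence[LeafletRecord], persistence: int = 2
) -> tuple[list[FlipFlopEvent], dict[int, int]]:
    """Leaflet-label changes that persist.

    An event is a lipid whose (bilayer, leaflet) label changes between
    consecutive frames and keeps the new label for at least ``persistence``
    frames (or to the end of the trajectory), which suppresses boundary
    flicker.  Returns the event list and per-bilayer counts.
    """
    if len(leaflets) < 2:
        raise ValidationError("need at least two frames of leaflet labels")
    mol_ids = leaflets[0].mol_ids
    labels = np.empty((len(leaflets), len(mol_ids)), dtype=object)
    for fi, rec in enumerate(leaflets):
        if not np.array_equal(rec.mol_ids, mol_ids):
            raise ValidationError("leaflet records cover different lipid sets")
        labels[fi] = [f"{b}:{l}" for b, l in zip(rec.bilayer, rec.leaflet)]
    events: list[FlipFlopEvent] = []
    counts: dict[int, int] = {}
    n_frames = len(leaflets)
    for j, mol in enumerate(mol_ids):
        seq = labels[:, j]
        for f in range(1, n_frames):
            if seq[f] == seq[f - 1]:
                continue
            horizon = min(n_frames, f + persistence)
            if not all(seq[g] == seq[f] for g in range(f, horizon)):
                continue
            b_from, leaf_from = seq[f - 1].split(":")
            b_to, leaf_to = seq[f].split(":")
            events.append(
                FlipFlopEvent(
                    mol_id=int(mol),
                    frame=f,
                    bilayer=int(b_to),
                    from_leaflet=leaf_from,
                    to_leaflet=leaf_to,
                )
            )
            counts[int(b_to)] = counts.get(int(b_to), 0) + 1
    return events, counts


# ---------------------------------------------------------------------------
# ethanol penetration
# ---------------------------------------------------------------------------


def ethanol_penetration(
    profile: DensityProfile,
    midplanes: np.ndarray,
    d_pp_value: float,
    lz: float,
    head_clearance: float = 0.45,
    etnl_key: str = "ETNL",
) -> float:
    """Ratio of the mean ETNL density near bilayer midplanes (|z - mid| <
    0.25 d_PP) to its mean density in the solvent slabs (beyond the
    head-group zone).  Returns 0 when there is no ethanol at all."""
    if etnl_key not in profile.densities:
        return 0.0
    rho = profile.densities[etnl_key]
    if np.all(rho == 0):
        return 0.0
    z = profile.z
    dist = np.min(
        np.abs(_min_image(z[:, None] - np.asarray(midplanes)[None, :], lz)), axis=1
    )
    core = dist < 0.25 * d_pp_value
    solvent = dist > (0.5 * d_pp_value + head_clearance)
    if not np.any(solvent):
        raise ValidationError("no solvent region in the profile")
    solvent_mean = float(rho[solvent].mean())
    if solvent_mean == 0:
        raise ValidationError("zero solvent ethanol density: ratio undefined")
    return float(rho[core].mean()) / solvent_mean
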