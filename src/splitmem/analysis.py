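"""Validation observables for bilayer trajectories.

Lateral diffusion follows the 2D Einstein relation: D is slope/4 of the
lateral (xy) mean squared displacement versus lag time, fitted over a linear
window.  Order parameters use the C-H definition S_CD = <(3 cos^2 theta -
1)/2> against the +z bilayer normal, with optional ideal-tetrahedral
hydrogen reconstruction for united-atom systems.  Density profiles are
mass-weighted histograms along z re-centred on the membrane COM.  All
quantities are in nm / ns / amu / degrees unless noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from splitmem.core import (
    LeafletAssignment,
    SystemFrame,
    Trajectory,
    assign_leaflets,
    membrane_com,
)

__all__ = [
    "APLResult",
    "DensityProfile",
    "DiffusionResult",
    "MSDSeries",
    "OrderParameterProfile",
    "PNAngleResult",
    "RDFResult",
    "area_per_lipid",
    "density_profile",
    "diffusion_time",
    "fit_diffusion",
    "lateral_msd",
    "molecule_com_series",
    "order_parameters",
    "pn_angle",
    "rdf",
    "select_atoms",
    "speedup",
    "thickness",
]

_AMU_PER_NM3_TO_KG_PER_M3 = 1.66053906660
_TETRA_HALF_ANGLE = np.deg2rad(109.47 / 2.0)


def select_atoms(
    table, species: set[str] | None = None, names: set[str] | None = None
) -> np.ndarray:
    """Boolean atom mask by residue-name and/or atom-name membership."""
    mask = np.ones(len(table), dtype=bool)
    if species is not None:
        mask &= np.array([str(r) in species for r in table.resnames])
    if names is not None:
        mask &= np.array([str(n) in names for n in table.names])
    return mask


# ---------------------------------------------------------------------------
# lateral diffusion


@dataclass
class MSDSeries:
    """Lateral (xy) MSD curve: msd[0] == 0, lag times strictly increasing."""

    lag_times: np.ndarray  # ns
    msd: np.ndarray  # nm^2
    n_origins: np.ndarray  # time origins x molecules contributing per lag


@dataclass
class DiffusionResult:
    D: float  # nm^2/ns
    D_err: float
    fit_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"negative diffusion coefficient {self.D}")


def molecule_com_series(
    traj: Trajectory, molecule_ids: list[int] | None = None
) -> np.ndarray:
    """Unwrapped per-molecule COM positions, shape (n_frames, n_mols, 3).

    Wrapped coordinates are unwrapped by accumulating minimum-image COM
    displacements between consecutive frames (valid while no molecule moves
    more than half a box length per frame).
    """
    table = traj.table
    slices = table.mol_slices
    if molecule_ids is None:
        molecule_ids = list(range(len(slices)))
    n_frames = len(traj)
    coms = np.empty((n_frames, len(molecule_ids), 3))
    weights = []
    for k, m in enumerate(molecule_ids):
        sl = slices[m]
        w = table.masses[sl]
        total = w.sum()
        if total <= 0:
            w = np.ones(sl.stop - sl.start)
            total = w.sum()
        weights.append((sl, w / total))
    for fi, frame in enumerate(traj):
        pos = frame.positions
        for k, (sl, w) in enumerate(weights):
            coms[fi, k] = w @ pos[sl]
    # unwrap
    boxes = np.array([f.box for f in traj])
    for fi in range(1, n_frames):
        delta = coms[fi] - coms[fi - 1]
        delta -= boxes[fi] * np.round(delta / boxes[fi])
        coms[fi] = coms[fi - 1] + delta
    return coms


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    n = len(x)
    f = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(f * np.conjugate(f))[:n].real
    return acf / (n - np.arange(n))


def _msd_fft_1particle(r: np.ndarray) -> np.ndarray:
    """All-origin MSD of one (N, d) series via the FFT identity."""
    n = len(r)
    d_sq = np.square(r).sum(axis=1)
    d_ext = np.append(d_sq, 0.0)
    s2 = sum(_autocorr_fft(r[:, i]) * (n - np.arange(n)) for i in range(r.shape[1]))
    q = 2.0 * d_sq.sum()
    s1 = np.zeros(n)
    counts = n - np.arange(n)
    for m in range(n):
        q = q - d_ext[m - 1] - d_ext[n - m]
        s1[m] = q
    return (s1 - 2.0 * s2) / counts


def lateral_msd(
    traj: Trajectory,
    selection: list[int] | set[str] | None = None,
    max_lag: float | None = None,
    drift_correction: str = "none",
    leaflets: LeafletAssignment | None = None,
) -> MSDSeries:
    """Lateral MSD averaged over molecules and all time origins.

    ``selection`` is a list of molecule ids or a set of species names
    (default: every molecule).  Frames must be uniformly spaced in time.
    """
    if drift_correction not in ("none", "system_com", "leaflet_com"):
        raise ValueError(f"unknown drift_correction {drift_correction!r}")
    if len(traj) < 2:
        raise ValueError("need at least two frames")
    table = traj.table
    if selection is None:
        mol_ids = list(range(table.n_molecules))
    elif isinstance(selection, (set, frozenset)):
        species = table.mol_species()
        mol_ids = [m for m, sp in enumerate(species) if sp in selection]
    else:
        mol_ids = list(selection)
    if not mol_ids:
        raise ValueError("selection resolves to no molecules")

    times = traj.times
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("lateral_msd requires uniformly spaced frames")
    dt = float(dts[0])

    coms = molecule_com_series(traj, mol_ids)[:, :, :2]
    if drift_correction == "system_com":
        coms = coms - coms.mean(axis=1, keepdims=True)
    elif drift_correction == "leaflet_com":
        if leaflets is None:
            leaflets = assign_leaflets(
                traj[0],
                {sp: "P" for sp in set(table.mol_species())},
            )
        for leaflet in ("upper", "lower"):
            cols = [
                k for k, m in enumerate(mol_ids)
                if leaflets.labels.get(m) == leaflet
            ]
            if cols:
                coms[:, cols, :] -= coms[:, cols, :].mean(axis=1, keepdims=True)

    n_frames = len(traj)
    n_lags = n_frames
    if max_lag is not None:
        n_lags = min(n_frames, int(round(max_lag / dt)) + 1)
    acc = np.zeros(n_frames)
    for k in range(coms.shape[1]):
        acc += _msd_fft_1particle(coms[:, k, :])
    msd = acc[:n_lags] / coms.shape[1]
    msd[0] = 0.0
    lag_times = np.arange(n_lags) * dt
    n_origins = (n_frames - np.arange(n_lags)) * coms.shape[1]
    return MSDSeries(lag_times=lag_times, msd=msd, n_origins=n_origins)


def fit_diffusion(
    msd: MSDSeries, window: tuple[float, float]
) -> DiffusionResult:
    """Least-squares line on MSD(tau) inside ``window``; D = slope / 4.

    The uncertainty is a two-halves block estimate: the window is split in
    two, each half fitted separately, and half the absolute difference of
    the two slopes/4 reported.
    """
    t_min, t_max = window
    mask = (msd.lag_times >= t_min) & (msd.lag_times <= t_max)
    if mask.sum() < 2:
        raise ValueError(
            f"fit window {window} contains {int(mask.sum())} points; need >= 2"
        )
    t = msd.lag_times[mask]
    y = msd.msd[mask]
    slope = np.polyfit(t, y, 1)[0]
    d_value = max(float(slope) / 4.0, 0.0)

    mid = len(t) // 2
    d_err = 0.0
    if mid >= 2 and len(t) - mid >= 2:
        s1 = np.polyfit(t[:mid], y[:mid], 1)[0]
        s2 = np.polyfit(t[mid:], y[mid:], 1)[0]
        d_err = abs(s1 - s2) / 8.0
    return DiffusionResult(D=d_value, D_err=float(d_err), fit_window=(t_min, t_max))


def diffusion_time(D: float, displacement: float = 20.0) -> float:
    """Time (us) for the lateral MSD to reach ``displacement``^2.

    tau = displacement^2 / (4 D), with D in nm^2/ns and displacement in nm.
    """
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    tau_ns = displacement**2 / (4.0 * D)
    return tau_ns / 1000.0


def speedup(D_split: float, D_standard: float) -> float:
    """Diffusion speedup ratio D_split / D_standard."""
    if D_standard <= 0 or D_split <= 0:
        raise ValueError("both diffusion coefficients must be > 0")
    return D_split / D_standard


# ---------------------------------------------------------------------------
# density profile


@dataclass
class DensityProfile:
    z_centers: np.ndarray  # nm, relative to membrane COM
    densities: dict[str, np.ndarray]  # kg/m^3
    bin_width: float


def density_profile(
    traj: Trajectory | SystemFrame,
    selections: dict[str, np.ndarray] | None = None,
    bin_width: float = 0.1,
) -> DensityProfile:
    """Mass density along z, re-centred per frame on the membrane COM."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    table = frames[0].table
    if selections is None:
        selections = {"all": np.ones(len(table), dtype=bool)}
    for label, mask in selections.items():
        if not np.any(mask):
            raise ValueError(f"selection {label!r} is empty")

    half = max(float(f.box[2]) for f in frames) / 2.0
    n_bins = int(np.ceil(2.0 * half / bin_width))
    edges = -half + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    acc = {label: np.zeros(n_bins) for label in selections}
    lipid = table.lipid_mask()
    com_sel = lipid if np.any(lipid) else np.ones(len(table), dtype=bool)
    for frame in frames:
        com = membrane_com(frame, com_sel)
        area = float(frame.box[0] * frame.box[1])
        z = frame.positions[:, 2] - com
        for label, mask in selections.items():
            hist, _ = np.histogram(
                z[mask], bins=edges, weights=table.masses[mask]
            )
            acc[label] += hist / (area * bin_width)
    densities = {
        label: a / len(frames) * _AMU_PER_NM3_TO_KG_PER_M3
        for label, a in acc.items()
    }
    return DensityProfile(z_centers=centers, densities=densities, bin_width=bin_width)


# ---------------------------------------------------------------------------
# order parameters


@dataclass
class OrderParameterProfile:
    """Signed S_CD per carbon position (1-based index along the chain)."""

    chain: str
    s_cd: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, s in self.s_cd.items():
            if abs(s) > 1.0 + 1e-9:
                raise ValueError(f"carbon {i}: |S_CD| = {abs(s)} > 1")


def _reconstructed_ch_vectors(carbons: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Ideal tetrahedral C-H unit vectors for interior carbons of a chain."""
    out = []
    for i in range(1, len(carbons) - 1):
        b1 = carbons[i - 1] - carbons[i]
        b2 = carbons[i + 1] - carbons[i]
        b1 /= np.linalg.norm(b1)
        b2 /= np.linalg.norm(b2)
        bisector = -(b1 + b2)
        nb = np.linalg.norm(bisector)
        w = np.cross(b1, b2)
        nw = np.linalg.norm(w)
        if nb < 1e-10 or nw < 1e-10:
            raise ValueError(f"degenerate chain geometry at carbon {i + 1}")
        bisector /= nb
        w /= nw
        h1 = np.cos(_TETRA_HALF_ANGLE) * bisector + np.sin(_TETRA_HALF_ANGLE) * w
        h2 = np.cos(_TETRA_HALF_ANGLE) * bisector - np.sin(_TETRA_HALF_ANGLE) * w
        out.append((i + 1, np.stack([h1, h2])))
    return out


def order_parameters(
    traj: Trajectory | SystemFrame,
    chain_definitions: dict[str, dict[str, list[str]]],
    hydrogen_mode: str = "reconstructed",
    normal: np.ndarray | None = None,
) -> dict[str, OrderParameterProfile]:
    """S_CD profiles per chain label (e.g. SN1/SN2).

    ``chain_definitions`` maps species -> chain label -> ordered carbon atom
    names.  ``reconstructed`` builds ideal tetrahedral hydrogens from the
    neighbouring carbons (united-atom friendly); ``explicit`` uses hydrogen
    atoms found within 0.125 nm of each carbon.
    """
    if hydrogen_mode not in ("reconstructed", "explicit"):
        raise ValueError(f"unknown hydrogen_mode {hydrogen_mode!r}")
    if normal is None:
        normal = np.array([0.0, 0.0, 1.0])
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    table = frames[0].table

    sums: dict[str, dict[int, float]] = {}
    counts: dict[str, dict[int, int]] = {}

    for frame in frames:
        for m, sl in enumerate(table.mol_slices):
            species = str(table.resnames[sl.start])
            if species not in chain_definitions:
                continue
            names = [str(n) for n in table.names[sl]]
            pos = frame.positions[sl]
            name_to_i = {}
            for i, nm in enumerate(names):
                name_to_i.setdefault(nm, i)
            for chain_label, carbon_names in chain_definitions[species].items():
                missing = [c for c in carbon_names if c not in name_to_i]
                if missing:
                    raise ValueError(
                        f"residue {species} (molecule {m}): missing chain "
                        f"carbons {missing}"
                    )
                carbons = np.array([pos[name_to_i[c]] for c in carbon_names])
                csum = sums.setdefault(chain_label, {})
                ccnt = counts.setdefault(chain_label, {})
                if hydrogen_mode == "reconstructed":
                    for ci, h_vecs in _reconstructed_ch_vectors(carbons):
                        cos_t = h_vecs @ normal
                        val = float(np.sum(1.5 * cos_t**2 - 0.5))
                        csum[ci] = csum.get(ci, 0.0) + val
                        ccnt[ci] = ccnt.get(ci, 0) + len(cos_t)
                else:
                    masses = table.masses[sl]
                    h_mask = masses < 1.5
                    h_pos = pos[h_mask]
                    for ci, cname in enumerate(carbon_names, start=1):
                        c = pos[name_to_i[cname]]
                        d = np.linalg.norm(h_pos - c, axis=1)
                        bonded = h_pos[d < 0.125]
                        if len(bonded) == 0:
                            continue
                        vec = bonded - c
                        vec /= np.linalg.norm(vec, axis=1)[:, None]
                        cos_t = vec @ normal
                        val = float(np.sum(1.5 * cos_t**2 - 0.5))
                        csum[ci] = csum.get(ci, 0.0) + val
                        ccnt[ci] = ccnt.get(ci, 0) + len(cos_t)

    profiles = {}
    for chain_label, csum in sums.items():
        ccnt = counts[chain_label]
        profiles[chain_label] = OrderParameterProfile(
            chain=chain_label,
            s_cd={i: csum[i] / ccnt[i] for i in sorted(csum)},
        )
    return profiles


# ---------------------------------------------------------------------------
# headgroup tilt, area, thickness


@dataclass
class PNAngleResult:
    angles: np.ndarray  # degrees, flattened over frames x lipids
    mean: float


def pn_angle(
    traj: Trajectory | SystemFrame,
    leaflets: LeafletAssignment | None = None,
    p_name: str = "P",
    n_name: str = "N",
) -> PNAngleResult:
    """Angle between the P->N vector and the outward leaflet normal
    (upper: +z, lower: -z), in degrees."""
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    table = frames[0].table
    if leaflets is None:
        anchors = {
            sp: p_name
            for sp in set(table.mol_species())
        }
        # only lipids that actually carry a P atom participate
        lipid_species = {
            str(table.resnames[sl.start])
            for sl in table.mol_slices
            if p_name in table.names[sl]
        }
        anchors = {sp: p_name for sp in lipid_species}
        leaflets = assign_leaflets(frames[0], anchors, lipid_species=lipid_species)

    skipped: set[str] = set()
    angles: list[float] = []
    for frame in frames:
        for m, sl in enumerate(table.mol_slices):
            if m not in leaflets.labels:
                continue
            names = table.names[sl]
            p_hits = np.nonzero(names == p_name)[0]
            n_hits = np.nonzero(names == n_name)[0]
            species = str(table.resnames[sl.start])
            if p_hits.size == 0 or n_hits.size == 0:
                skipped.add(species)
                continue
            vec = (
                frame.positions[sl.start + n_hits[0]]
                - frame.positions[sl.start + p_hits[0]]
            )
            nz = 1.0 if leaflets.labels[m] == "upper" else -1.0
            cos_t = vec[2] * nz / np.linalg.norm(vec)
            angles.append(float(np.degrees(np.arccos(np.clip(cos_t, -1, 1)))))
    for sp in sorted(skipped):
        warnings.warn(f"species {sp!r} lacks {p_name}/{n_name}; skipped", stacklevel=2)
    if not angles:
        raise ValueError("no lipids with both P and N atoms found")
    arr = np.array(angles)
    return PNAngleResult(angles=arr, mean=float(arr.mean()))


@dataclass
class APLResult:
    series: np.ndarray  # nm^2 per frame
    mean: float
    sem: float


def area_per_lipid(
    traj: Trajectory | SystemFrame, n_per_leaflet: int
) -> APLResult:
    """Box xy-area divided by lipids per leaflet, per frame."""
    if n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be > 0")
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    series = np.array([f.box[0] * f.box[1] / n_per_leaflet for f in frames])
    sem = float(series.std(ddof=1) / np.sqrt(len(series))) if len(series) > 1 else 0.0
    return APLResult(series=series, mean=float(series.mean()), sem=sem)


def thickness(
    traj: Trajectory | SystemFrame, reference_atom_names: set[str]
) -> np.ndarray:
    """|mean z(upper refs) - mean z(lower refs)| per frame, nm.

    Reference atoms are assigned to leaflets by the sign of z relative to
    the membrane COM, per frame.
    """
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    table = frames[0].table
    lipid = table.lipid_mask()
    name_mask = np.array([str(n) in reference_atom_names for n in table.names])
    mask = lipid & name_mask
    if not np.any(mask):
        raise ValueError(f"no lipid atoms named {sorted(reference_atom_names)}")
    out = []
    for frame in frames:
        com = membrane_com(frame)
        z = frame.positions[mask, 2]
        upper = z[z > com]
        lower = z[z <= com]
        if upper.size == 0 or lower.size == 0:
            raise ValueError("reference atoms found in only one leaflet")
        out.append(abs(upper.mean() - lower.mean()))
    return np.array(out)


# ---------------------------------------------------------------------------
# radial distribution function


@dataclass
class RDFResult:
    r_centers: np.ndarray  # nm
    g: np.ndarray
    mode: str


def rdf(
    traj: Trajectory | SystemFrame,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    r_max: float,
    dr: float,
    mode: str = "3D",
) -> RDFResult:
    """Pair distribution normalised by the ideal-gas expectation.

    ``3D`` uses full minimum-image distances and spherical shells;
    ``lateral_2D`` projects onto xy and normalises by annuli.
    """
    if mode not in ("3D", "lateral_2D"):
        raise ValueError(f"unknown mode {mode!r}")
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    sel_a = np.asarray(sel_a, dtype=bool)
    sel_b = np.asarray(sel_b, dtype=bool)
    idx_a = np.nonzero(sel_a)[0]
    idx_b = np.nonzero(sel_b)[0]
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty RDF selection")

    n_bins = int(np.ceil(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(n_bins)
    norm = np.zeros(n_bins)

    same = sel_a.shape == sel_b.shape and np.array_equal(sel_a, sel_b)
    for frame in frames:
        box = frame.box
        limit = min(box[:2]) / 2.0 if mode == "lateral_2D" else min(box) / 2.0
        if r_max > limit + 1e-9:
            raise ValueError(
                f"r_max {r_max} exceeds half the smallest box dimension {limit:.3f}"
            )
        pa = frame.positions[idx_a]
        pb = frame.positions[idx_b]
        delta = pa[:, None, :] - pb[None, :, :]
        if mode == "lateral_2D":
            delta = delta[:, :, :2]
            delta -= box[:2] * np.round(delta / box[:2])
        else:
            delta -= box * np.round(delta / box)
        dist = np.sqrt(np.square(delta).sum(axis=-1))
        if same:
            np.fill_diagonal(dist, np.inf)
        else:
            # mask any atom that is in both selections
            shared = np.intersect1d(idx_a, idx_b)
            for s in shared:
                i = np.nonzero(idx_a == s)[0][0]
                j = np.nonzero(idx_b == s)[0][0]
                dist[i, j] = np.inf
        h, _ = np.histogram(dist[np.isfinite(dist)], bins=edges)
        hist += h

        n_a = idx_a.size
        n_b_eff = idx_b.size - (1 if same else 0)
        if mode == "lateral_2D":
            space = float(box[0] * box[1])
            shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        else:
            space = float(box[0] * box[1] * box[2])
            shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        norm += n_a * n_b_eff / space * shell

    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    return RDFResult(r_centers=centers, g=g, mode=mode)
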