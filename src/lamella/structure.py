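"""Structural observables of lipid bilayers.

Everything here consumes sequences of :class:`~lamella.io.Frame` and the
species conventions in :class:`~lamella.topology.LipidTopology`:

* C-H bond order parameters S_CH = <(3 cos^2 theta - 1)/2>,
* headgroup / acyl-chain tilt-angle distributions,
* area per lipid from a periodic 2-D Voronoi tessellation of the
  phosphorus positions,
* bilayer thickness d_P (phosphorus plane separation),
* mass density profiles along the bilayer normal,
* intermolecular contact counts at a distance cutoff,
* lateral (2-D, per-leaflet) radial distribution functions,
* like-lipid cluster statistics from the contact graph.

Statistical errors treat frames as independent samples; no autocorrelation
correction is applied.  Averages over simulation repeats are taken by
pooling the repeats' frame sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi, cKDTree

from .io import Box, Frame, LeafletAssignment, assign_leaflets, minimum_image_displacement
from .masses import atom_mass
from .topology import LipidTopology

logger = logging.getLogger(__name__)

__all__ = [
    "OrderParameterProfile",
    "TiltDistribution",
    "AreaPerLipid",
    "ThicknessResult",
    "DensityProfile",
    "ContactSummary",
    "RdfResult",
    "ClusterStats",
    "order_parameters",
    "tilt_distribution",
    "voronoi_apl",
    "bilayer_thickness",
    "density_profile",
    "contact_counts",
    "lateral_rdf",
    "like_lipid_clusters",
]

Selection = Sequence[tuple[str, str | None]]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class OrderParameterProfile:
    species_name: str
    labels: tuple[str, ...]
    s_ch: np.ndarray          # signed, per site
    s_ch_abs: np.ndarray      # |S_CH| of the per-site mean
    stderr: np.ndarray        # standard error over frames

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species_name, "site": self.labels,
                             "s_ch": self.s_ch, "abs_s_ch": self.s_ch_abs,
                             "stderr": self.stderr})


@dataclass(frozen=True)
class TiltDistribution:
    vector_kind: str
    species_name: str
    bin_edges: np.ndarray     # degrees, [0, 180]
    probability: np.ndarray   # sums to 1
    mean: float               # degrees, from raw angles
    mode: float               # degrees, center of the maximum bin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class AreaPerLipid:
    per_species: dict[str, float]          # mean cell area, nm^2
    per_species_sd: dict[str, float]       # SD of the per-frame means
    per_species_sem: dict[str, float]      # standard error over frames
    breakdown: pd.DataFrame                # frame, leaflet, species, mean_area, n


@dataclass(frozen=True)
class ThicknessResult:
    mean: float                # nm
    sd: float                  # SD over frames
    sem: float                 # standard error over frames
    per_frame: np.ndarray


@dataclass(frozen=True)
class DensityProfile:
    label: str
    bin_centers: np.ndarray    # nm, bilayer centre at 0
    density: np.ndarray        # kg/m^3
    bin_width: float


@dataclass(frozen=True)
class ContactSummary:
    pair_label: str
    mean_contacts_per_a: float
    mean_contacts_per_b: float
    cutoff: float
    total_pairs_per_frame: float
    intra_species: bool


@dataclass(frozen=True)
class RdfResult:
    pair_label: str
    bin_centers: np.ndarray    # nm
    g: np.ndarray              # dimensionless
    cumulative: np.ndarray     # mean neighbour count N(r)


@dataclass(frozen=True)
class ClusterStats:
    species_name: str
    size_histogram: dict[int, int]
    mean_size: float
    max_size: int


# ---------------------------------------------------------------------------
# selection helpers


def _species_positions(frame: Frame, species: str, atom: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions of one named atom for every lipid of a species.

    Returns (residue_indices, positions) sorted by residue index; raises if
    any lipid of the species lacks the atom.
    """
    mask = frame.select(species, atom)
    res = frame.residue_index[mask]
    pos = frame.positions[mask]
    n_lipids = len(np.unique(frame.residue_index[frame.select(species)]))
    if len(res) != n_lipids:
        raise ValueError(f"atom {atom!r} missing for some {species} lipids "
                         f"({len(res)} found, {n_lipids} lipids)")
    order = np.argsort(res, kind="stable")
    return res[order], pos[order]


def _selection_mask(frame: Frame, selection: Selection) -> np.ndarray:
    mask = np.zeros(frame.n_atoms, dtype=bool)
    for res_name, atom_name in selection:
        mask |= frame.select(res_name, atom_name)
    return mask


def _wrap(pos: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    wrapped = np.mod(pos, lengths)
    wrapped[wrapped >= lengths] = 0.0
    return wrapped


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


# ---------------------------------------------------------------------------
# order parameters


def order_parameters(frames: Sequence[Frame], topology: LipidTopology,
                     sites: Sequence[str] | None = None,
                     labels: Sequence[str] | None = None) -> OrderParameterProfile:
    """C-H bond order parameters S_CH for the requested carbon sites.

    For every explicit C-H bond the angle theta to the bilayer normal (the
    z axis) enters S_CH = <(3 cos^2 theta - 1)/2>.  Averaging is performed
    first over the hydrogens of a carbon, then over lipids (giving one value
    per frame) and finally over frames; the frame-to-frame scatter yields
    the standard error.
    """
    if sites is None:
        sites = list(topology.sn1_chain)
    sites = list(sites)
    if labels is None:
        labels = sites
    missing = [s for s in sites if not topology.ch_bonds.get(s)]
    if missing:
        raise ValueError(f"no C-H bonds defined for sites: {', '.join(missing)}")
    if not frames:
        raise ValueError("no frames supplied")

    per_frame = np.empty((len(frames), len(sites)))
    for fi, frame in enumerate(frames):
        lengths = frame.box.lengths
        for si, site in enumerate(sites):
            _, c_pos = _species_positions(frame, topology.species_name, site)
            if len(c_pos) == 0:
                raise ValueError(f"no {topology.species_name} lipids in frame {fi}")
            h_means = []
            for h_name in topology.ch_bonds[site]:
                _, h_pos = _species_positions(frame, topology.species_name, h_name)
                vec = minimum_image_displacement(h_pos, c_pos, frame.box)
                norm = np.linalg.norm(vec, axis=1)
                cos_t = vec[:, 2] / norm
                h_means.append(0.5 * (3.0 * cos_t**2 - 1.0))
            per_lipid = np.mean(h_means, axis=0)
            per_frame[fi, si] = per_lipid.mean()

    mean = per_frame.mean(axis=0)
    stderr = np.array([_sem(per_frame[:, si]) for si in range(len(sites))])
    return OrderParameterProfile(topology.species_name, tuple(labels),
                                 mean, np.abs(mean), stderr)


# ---------------------------------------------------------------------------
# tilt angles


def tilt_distribution(frames: Sequence[Frame], topology: LipidTopology,
                      vector_kind: str, bin_width: float = 1.0,
                      leaflet_topologies: Mapping[str, LipidTopology] | None = None,
                      ) -> TiltDistribution:
    """Distribution of the angle between a lipid segment vector and the
    leaflet's outward normal.

    ``vector_kind``: ``"head"`` uses the topology's head vector (P -> N for
    PC, P -> serine carbon for PS); ``"sn1"`` / ``"sn2"`` use the chain
    director pointing from the terminal carbon toward the glycerol end, so
    that an extended chain parallel to the membrane normal reads ~0 degrees.
    The reference normal is +z for the upper leaflet and -z for the lower,
    pooling both leaflets into a common [0, 180] degree frame.
    """
    if vector_kind == "head":
        a_name, b_name = topology.head_vector_atoms
    elif vector_kind == "sn1":
        a_name, b_name = topology.sn1_chain[-1], topology.sn1_chain[0]
    elif vector_kind == "sn2":
        a_name, b_name = topology.sn2_chain[-1], topology.sn2_chain[0]
    else:
        raise ValueError("vector_kind must be 'head', 'sn1' or 'sn2'")
    if leaflet_topologies is None:
        leaflet_topologies = {topology.species_name: topology}
    n_bins = max(1, int(round(180.0 / bin_width)))
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts = np.zeros(n_bins)
    angle_sum = 0.0
    n_angles = 0

    for frame in frames:
        leaflets = assign_leaflets(frame, leaflet_topologies)
        res_a, pos_a = _species_positions(frame, topology.species_name, a_name)
        res_b, pos_b = _species_positions(frame, topology.species_name, b_name)
        if not np.array_equal(res_a, res_b):
            raise ValueError("vector atoms belong to different lipid sets")
        vec = minimum_image_displacement(pos_b, pos_a, frame.box)
        norm = np.linalg.norm(vec, axis=1)
        zero = norm < 1e-12
        if zero.any():
            raise ValueError(f"zero-length {vector_kind} vector for residue "
                             f"{int(res_a[np.argmax(zero)])}")
        sign = np.array([1.0 if leaflets.leaflet_of[int(r)] == "upper" else -1.0
                         for r in res_a])
        cos_t = np.clip(sign * vec[:, 2] / norm, -1.0, 1.0)
        angles = np.degrees(np.arccos(cos_t))
        hist, _ = np.histogram(angles, bins=edges)
        counts += hist
        angle_sum += angles.sum()
        n_angles += len(angles)

    if n_angles == 0:
        raise ValueError("no lipids found for tilt analysis")
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[int(np.argmax(counts))])
    return TiltDistribution(vector_kind, topology.species_name, edges, prob,
                            mean=angle_sum / n_angles, mode=mode)


# ---------------------------------------------------------------------------
# Voronoi area per lipid


def _periodic_voronoi_areas(xy: np.ndarray, box: Box,
                            jitter_scale: float = 1e-6) -> np.ndarray:
    """Cell areas of the periodic 2-D Voronoi diagram of the given seeds.

    Seeds are replicated into the 8 neighbouring lateral images; only the
    central copies' cells are measured, which is exact for orthorhombic
    boxes.  Coincident seeds are perturbed by a deterministic ~1e-6 nm
    jitter (logged) to break tessellation degeneracy.
    """
    lengths = box.lengths[:2]
    xy = _wrap(np.array(xy, dtype=float), lengths)
    n = len(xy)
    if n < 3:
        raise ValueError("periodic Voronoi needs at least 3 seeds per leaflet")

    rounded = np.round(xy / jitter_scale).astype(np.int64)
    _, first_idx, inverse = np.unique(rounded, axis=0, return_index=True,
                                      return_inverse=True)
    if len(first_idx) < n:
        logger.warning("perturbing %d coincident Voronoi seeds", n - len(first_idx))
        rng = np.random.default_rng(8191)
        jitter = rng.normal(scale=jitter_scale, size=xy.shape)
        dup = np.ones(n, dtype=bool)
        dup[first_idx] = False
        xy = xy + jitter * dup[:, None]
        xy = _wrap(xy, lengths)

    offsets = np.array([(ix, iy) for ix in (-1, 0, 1) for iy in (-1, 0, 1)
                        if (ix, iy) != (0, 0)], dtype=float) * lengths
    tiled = np.vstack([xy] + [xy + off for off in offsets])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell for a central seed; "
                               "box replication failed")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    total = areas.sum()
    if abs(total - box.cross_section) > 1e-6 * box.cross_section:
        raise RuntimeError(f"Voronoi areas sum to {total:.8f} nm^2, expected "
                           f"{box.cross_section:.8f} nm^2")
    return areas


def voronoi_apl(frames: Sequence[Frame],
                topologies: Mapping[str, LipidTopology],
                leaflets: LeafletAssignment | None = None) -> AreaPerLipid:
    """Per-species area per lipid from periodic Voronoi tessellation.

    For every frame and leaflet the lipids' phosphorus atoms are projected
    onto the xy plane and tessellated under lateral periodicity; the
    per-species APL is the mean cell area over lipids, leaflets and frames.
    """
    rows = []
    per_frame_species: dict[str, list[float]] = {}
    for fi, frame in enumerate(frames):
        assignment = leaflets if leaflets is not None else assign_leaflets(frame, topologies)
        species_arr = []
        res_arr = []
        pos_arr = []
        for species, topo in topologies.items():
            if not frame.select(species).any():
                continue
            res, pos = _species_positions(frame, species, topo.phosphorus_atom)
            species_arr.append(np.full(len(res), species, dtype="U8"))
            res_arr.append(res)
            pos_arr.append(pos)
        species_all = np.concatenate(species_arr)
        res_all = np.concatenate(res_arr)
        pos_all = np.vstack(pos_arr)
        frame_areas: dict[str, list[np.ndarray]] = {}
        for leaflet in ("upper", "lower"):
            members = np.array([assignment.leaflet_of[int(r)] == leaflet
                                for r in res_all])
            if members.sum() < 3:
                raise ValueError(f"{leaflet} leaflet has fewer than 3 lipids")
            areas = _periodic_voronoi_areas(pos_all[members, :2], frame.box)
            leaflet_species = species_all[members]
            for species in np.unique(leaflet_species):
                sel = areas[leaflet_species == species]
                rows.append({"frame": fi, "leaflet": leaflet, "species": str(species),
                             "mean_area": float(sel.mean()), "n": int(len(sel))})
                frame_areas.setdefault(str(species), []).append(sel)
        for species, chunks in frame_areas.items():
            value = float(np.concatenate(chunks).mean())
            per_frame_species.setdefault(species, []).append(value)

    per_species = {s: float(np.mean(v)) for s, v in per_frame_species.items()}
    per_species_sd = {s: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                      for s, v in per_frame_species.items()}
    per_species_sem = {s: _sem(np.asarray(v)) for s, v in per_frame_species.items()}
    return AreaPerLipid(per_species, per_species_sd, per_species_sem,
                        pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# thickness


def bilayer_thickness(frames: Sequence[Frame],
                      topologies: Mapping[str, LipidTopology]) -> ThicknessResult:
    """Bilayer thickness d_P: mean z-separation of the two phosphorus planes."""
    values = []
    for frame in frames:
        assignment = assign_leaflets(frame, topologies)
        z_by_leaflet: dict[str, list[float]] = {"upper": [], "lower": []}
        for species, topo in topologies.items():
            if not frame.select(species).any():
                continue
            res, pos = _species_positions(frame, species, topo.phosphorus_atom)
            for r, z in zip(res, pos[:, 2]):
                z_by_leaflet[assignment.leaflet_of[int(r)]].append(z)
        if not z_by_leaflet["upper"] or not z_by_leaflet["lower"]:
            raise ValueError("both leaflets must contain phosphorus atoms")
        values.append(float(np.mean(z_by_leaflet["upper"]) - np.mean(z_by_leaflet["lower"])))
    values = np.asarray(values)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return ThicknessResult(float(values.mean()), sd, _sem(values), values)


# ---------------------------------------------------------------------------
# density profiles


def density_profile(frames: Sequence[Frame], selection: Selection,
                    topologies: Mapping[str, LipidTopology],
                    bin_width: float = 0.1, label: str | None = None) -> DensityProfile:
    """Mass density of the selected atoms along z, bilayer centre at z = 0.

    Each frame is re-centred at the mean z of all lipid phosphorus atoms
    before binning; masses come from the standard atomic mass table keyed by
    element inferred from the atom name (1 u/nm^3 = 1.66054 kg/m^3).
    """
    if not frames:
        raise ValueError("no frames supplied")
    lz = float(frames[0].box.lengths[2])
    n_bins = max(1, int(np.ceil(lz / bin_width)))
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    width = edges[1] - edges[0]
    accum = np.zeros(n_bins)
    for frame in frames:
        assignment = assign_leaflets(frame, topologies)
        mask = _selection_mask(frame, selection)
        if not mask.any():
            raise ValueError("density selection matches no atoms")
        masses = np.array([atom_mass(str(a), str(r))
                           for a, r in zip(frame.atom_name[mask],
                                           frame.residue_name[mask])])
        z = frame.positions[mask, 2] - assignment.bilayer_center_z
        z = z - lz * np.round(z / lz)       # wrap into [-lz/2, lz/2]
        hist, _ = np.histogram(z, bins=edges, weights=masses)
        vol = width * frame.box.cross_section   # nm^3
        accum += hist * 1.66053906660 / vol     # u/nm^3 -> kg/m^3
    density = accum / len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel_label = label or "+".join(f"{r}:{a or '*'}" for r, a in selection)
    return DensityProfile(sel_label, centers, density, float(width))


# ---------------------------------------------------------------------------
# contacts


def _molecule_contact_pairs(frame: Frame, mask_a: np.ndarray, mask_b: np.ndarray,
                            cutoff: float) -> set[tuple[int, int]]:
    """Distinct (residue_a, residue_b) pairs with any atom pair within cutoff.

    Uses a periodic k-d tree (cell-list equivalent); self pairs excluded.
    """
    lengths = frame.box.lengths
    pos_a = _wrap(frame.positions[mask_a].copy(), lengths)
    pos_b = _wrap(frame.positions[mask_b].copy(), lengths)
    res_a = frame.residue_index[mask_a]
    res_b = frame.residue_index[mask_b]
    if len(pos_a) == 0 or len(pos_b) == 0:
        return set()
    tree_a = cKDTree(pos_a, boxsize=lengths)
    tree_b = cKDTree(pos_b, boxsize=lengths)
    pairs = set()
    for ia, neighbours in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        ra = int(res_a[ia])
        for ib in neighbours:
            rb = int(res_b[ib])
            if ra != rb:
                pairs.add((ra, rb))
    return pairs


def contact_counts(frames: Sequence[Frame], selection_a: Selection,
                   selection_b: Selection, cutoff: float = 0.6,
                   pair_label: str | None = None) -> ContactSummary:
    """Mean number of molecular contacts per molecule of the first group.

    Two molecules (residues) are in contact when their minimum inter-atomic
    minimum-image distance is within the cutoff (default 0.6 nm).  When the
    two selections coincide, unordered same-group pairs are counted once and
    each contact contributes to both partners.
    """
    intra = set(selection_a) == set(selection_b)
    per_frame_a, per_frame_b, per_frame_pairs = [], [], []
    for frame in frames:
        mask_a = _selection_mask(frame, selection_a)
        mask_b = _selection_mask(frame, selection_b)
        if not mask_a.any() or not mask_b.any():
            raise ValueError("contact selection matches no atoms")
        n_mol_a = len(np.unique(frame.residue_index[mask_a]))
        n_mol_b = len(np.unique(frame.residue_index[mask_b]))
        pairs = _molecule_contact_pairs(frame, mask_a, mask_b, cutoff)
        if intra:
            unordered = {tuple(sorted(p)) for p in pairs}
            n_pairs = len(unordered)
            per_frame_a.append(2.0 * n_pairs / n_mol_a)
            per_frame_b.append(2.0 * n_pairs / n_mol_b)
        else:
            n_pairs = len(pairs)
            per_frame_a.append(n_pairs / n_mol_a)
            per_frame_b.append(n_pairs / n_mol_b)
        per_frame_pairs.append(n_pairs)
    label = pair_label or "A-B"
    return ContactSummary(label, float(np.mean(per_frame_a)),
                          float(np.mean(per_frame_b)), cutoff,
                          float(np.mean(per_frame_pairs)), intra)


# ---------------------------------------------------------------------------
# lateral RDF


def lateral_rdf(frames: Sequence[Frame],
                topologies: Mapping[str, LipidTopology],
                species_a: str, species_b: str,
                bin_width: float = 0.05, r_max: float | None = None) -> RdfResult:
    """2-D radial distribution function of phosphorus atoms within leaflets.

    g(r) is normalised by the ideal-gas annulus count at the leaflet's mean
    lateral density of species B; N(r) is the mean cumulative neighbour
    count.  The range is capped at half the shorter lateral box length.
    """
    if not frames:
        raise ValueError("no frames supplied")
    lengths0 = frames[0].box.lengths
    half_box = 0.5 * float(min(lengths0[0], lengths0[1]))
    if r_max is None:
        r_max = half_box
    elif r_max > half_box:
        warnings.warn(f"r_max {r_max} nm exceeds half the lateral box; "
                      f"truncated to {half_box} nm")
        r_max = half_box
    n_bins = max(1, int(np.floor(r_max / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts = np.zeros(n_bins)
    expected = np.zeros(n_bins)
    n_ref_total = 0
    same = species_a == species_b

    for frame in frames:
        assignment = assign_leaflets(frame, topologies)
        area = frame.box.cross_section
        lat = frame.box.lengths[:2]
        res_a, pos_a = _species_positions(frame, species_a,
                                          topologies[species_a].phosphorus_atom)
        res_b, pos_b = _species_positions(frame, species_b,
                                          topologies[species_b].phosphorus_atom)
        for leaflet in ("upper", "lower"):
            in_a = np.array([assignment.leaflet_of[int(r)] == leaflet for r in res_a])
            in_b = np.array([assignment.leaflet_of[int(r)] == leaflet for r in res_b])
            n_a, n_b = int(in_a.sum()), int(in_b.sum())
            if n_a == 0 or n_b == 0:
                continue
            xa = pos_a[in_a, :2]
            xb = pos_b[in_b, :2]
            delta = xa[:, None, :] - xb[None, :, :]
            delta -= lat * np.round(delta / lat)
            dist = np.sqrt((delta ** 2).sum(axis=-1))
            if same:
                np.fill_diagonal(dist, np.inf)
            hist, _ = np.histogram(dist.ravel(), bins=edges)
            counts += hist
            rho_b = (n_b - (1 if same else 0)) / area
            annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
            expected += n_a * rho_b * annulus
            n_ref_total += n_a

    if n_ref_total == 0:
        raise ValueError(f"species {species_a}/{species_b} never share a leaflet")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    cumulative = np.cumsum(counts) / n_ref_total
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfResult(f"{species_a}-{species_b}", centers, g, cumulative)


# ---------------------------------------------------------------------------
# clusters


def like_lipid_clusters(frame: Frame,
                        topologies: Mapping[str, LipidTopology],
                        species: str, cutoff: float = 0.6,
                        leaflets: LeafletAssignment | None = None) -> ClusterStats:
    """Connected-component statistics of the same-species contact graph.

    Within each leaflet, lipids of the species are nodes; an edge joins two
    lipids whose minimum inter-atomic distance is within the contact cutoff.
    Component sizes from the two leaflets are pooled.
    """
    if not frame.select(species).any():
        raise ValueError(f"species {species} not present in frame")
    assignment = leaflets if leaflets is not None else assign_leaflets(frame, topologies)
    sizes: list[int] = []
    species_res = np.unique(frame.residue_index[frame.select(species)])
    for leaflet in ("upper", "lower"):
        members = np.array([r for r in species_res
                            if assignment.leaflet_of[int(r)] == leaflet])
        if len(members) == 0:
            continue
        mask = frame.select(species) & np.isin(frame.residue_index, members)
        pairs = _molecule_contact_pairs(frame, mask, mask, cutoff)
        index = {int(r): i for i, r in enumerate(members)}
        n = len(members)
        if pairs:
            rows, cols = zip(*[(index[a], index[b]) for a, b in pairs])
            adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        else:
            adj = sparse.coo_matrix((n, n))
        n_comp, labels = connected_components(adj, directed=False)
        sizes.extend(np.bincount(labels, minlength=n_comp).tolist())
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    return ClusterStats(species, hist, float(np.mean(sizes)), int(max(sizes)))
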