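"""Synthetic bilayer configurations and isotherm families with known truth.

The generator builds idealised bilayer frames whose every configured
observable — per-species area per lipid, phosphorus plane separation,
headgroup/chain tilt laws, per-site C-H order parameters, ion and water
z-distributions — is known exactly, so each analysis stage can be verified
by parameter recovery.  Frames are independent redraws of the same
statistical ensemble, not dynamics: frame-to-frame correlation is zero by
construction and standard errors scale as 1/sqrt(n_frames).

A lipid is built from only the atoms the analyses touch: the phosphorus,
the head-vector terminus, straight-rod acyl chains at a fixed tilt, and
C-H hydrogen pairs placed on a cone whose polar angle encodes the target
order parameter, theta = arccos(sqrt((2 S + 1) / 3)).  Water is carried by
single-site "MW" pseudo-atoms (full molecular mass) and K+ counterions
follow Gaussian z-laws near the two headgroup planes.

Isotherm families are exponential compression laws A(pi) = A0 exp(-pi/K),
for which the compression modulus is exactly K at every pressure, plus an
optional constant excess-area term for mixtures, for which the excess free
energy of mixing has the closed form 0.6022 * a * pi*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import Box, Frame, write_trajectory
from .monolayer import KJ_PER_MOL_PER_MN_NM, Isotherm
from .topology import LipidTopology, default_topologies

__all__ = [
    "TiltLaw",
    "BilayerSpec",
    "IsothermSpec",
    "generate_bilayer",
    "generate_isotherms",
    "write_bilayer",
    "ch_cone_angle",
]

_HEAD_BOND_LENGTH = 0.45   # nm, P -> head-vector terminus
_CH_BOND_LENGTH = 0.109    # nm
_CHAIN_STEP = 0.125        # nm between successive chain carbons
_CHAIN_OFFSET = 0.25       # nm from P down to the first chain carbon
_WATER_GAP = 0.2           # nm clearance between P plane and water slab


def ch_cone_angle(s: float) -> float:
    """Polar angle (radians) whose fixed-cone order parameter equals ``s``.

    Inverts S = (3 cos^2 theta - 1)/2 for theta in [0, pi/2].
    """
    if not -0.5 <= s <= 1.0:
        raise ValueError("order parameter must lie in [-0.5, 1]")
    return math.acos(math.sqrt((2.0 * s + 1.0) / 3.0))


@dataclass(frozen=True)
class TiltLaw:
    """Polar-angle law for a lipid segment vector.

    ``kind`` is ``"cone"`` (delta function at ``angle_deg``; exact
    expectations) or ``"gaussian"`` (normal polar angle with ``sigma_deg``,
    reflected into [0, 180]; for mode-recovery tests).  Azimuth is always
    uniform.
    """

    angle_deg: float
    kind: str = "cone"
    sigma_deg: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "cone":
            return np.full(n, self.angle_deg)
        if self.kind == "gaussian":
            theta = rng.normal(self.angle_deg, self.sigma_deg, size=n)
            theta = np.abs(theta)                      # reflect at 0
            theta = 180.0 - np.abs(180.0 - theta)      # reflect at 180
            return theta
        raise ValueError(f"unknown tilt law kind {self.kind!r}")


@dataclass
class BilayerSpec:
    """Ground-truth parameters of a synthetic bilayer trajectory.

    Defaults mirror the study conditions the analyses are meant for:
    100 lipids per leaflet, 100 statistically independent frames, 0.1 nm
    vertical and 0.05 nm lateral positional noise, 50 waters per lipid and
    one K+ counterion per anionic lipid.
    """

    n_per_leaflet: dict[str, int]              # species -> lipids per leaflet
    apl: dict[str, float]                      # nm^2 per species
    d_p: float                                 # nm, P plane separation
    head_tilt: dict[str, TiltLaw] = field(default_factory=dict)
    chain_tilt: dict[str, float] = field(default_factory=dict)   # degrees
    s_ch: dict[str, dict[str, float]] = field(default_factory=dict)
    lateral_jitter: float = 0.05               # nm
    z_sigma: float = 0.1                       # nm
    n_frames: int = 100
    waters_per_lipid: float = 50.0
    counterion_species: str = "POPS"           # species neutralised by K+
    ion_z_offset: float = 0.3                  # nm beyond the P plane
    ion_z_sigma: float = 0.25                  # nm
    water_pad: float = 2.0                     # nm of water each side
    arrangement: str = "mixed"                 # or "clustered"
    include_chains: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_leaflet:
            raise ValueError("at least one lipid species required")
        for species, n in self.n_per_leaflet.items():
            if n < 0:
                raise ValueError(f"negative lipid count for {species}")
            if species not in self.apl:
                raise ValueError(f"no APL given for {species}")
            if self.apl[species] <= 0:
                raise ValueError(f"APL for {species} must be positive")
        if self.d_p <= 0:
            raise ValueError("d_p must be positive")
        for species, sites in self.s_ch.items():
            for site, s in sites.items():
                if not -0.5 <= s <= 1.0:
                    raise ValueError(f"S target {s} for {species}/{site} "
                                     "outside [-0.5, 1]")
        if self.arrangement not in ("mixed", "clustered"):
            raise ValueError("arrangement must be 'mixed' or 'clustered'")

    @property
    def n_lipids_leaflet(self) -> int:
        return sum(self.n_per_leaflet.values())

    @property
    def mean_apl(self) -> float:
        n = self.n_lipids_leaflet
        return sum(self.n_per_leaflet[s] * self.apl[s] for s in self.n_per_leaflet) / n

    @property
    def x_anionic(self) -> float:
        n = self.n_lipids_leaflet
        return self.n_per_leaflet.get(self.counterion_species, 0) / n


def _lattice_shape(n: int) -> tuple[int, int]:
    """Near-square factorisation nx * ny = n (nx <= ny)."""
    nx = int(math.isqrt(n))
    while nx > 1 and n % nx:
        nx -= 1
    return nx, n // nx


def _unit_vectors(theta_deg: np.ndarray, phi: np.ndarray, sign: float) -> np.ndarray:
    """Unit vectors at polar angle theta from the leaflet's outward normal."""
    theta = np.radians(theta_deg)
    sin_t = np.sin(theta)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi),
                            sign * np.cos(theta)])


def generate_bilayer(spec: BilayerSpec,
                     topologies: Mapping[str, LipidTopology] | None = None,
                     ) -> tuple[list[Frame], dict]:
    """Build a synthetic bilayer trajectory and its ground-truth record.

    Returns ``(frames, truth)`` where ``truth`` stores every configured
    observable on the scale the corresponding analysis reports it.
    Identical spec and seed give bit-identical output.
    """
    if topologies is None:
        topologies = default_topologies()
    for species in spec.n_per_leaflet:
        if species not in topologies:
            raise KeyError(f"no topology for species {species!r}")

    rng = np.random.default_rng(spec.seed)
    n_leaf = spec.n_lipids_leaflet
    nx, ny = _lattice_shape(n_leaf)
    spacing = math.sqrt(spec.mean_apl)
    lx, ly = nx * spacing, ny * spacing
    lz = spec.d_p + 2.0 * spec.water_pad
    center = lz / 2.0
    box = Box(np.array([lx, ly, lz]))

    # fixed lattice sites (row-major) and a fixed species assignment per leaflet
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sites = np.column_stack([(gx.ravel() + 0.5) * spacing,
                             (gy.ravel() + 0.5) * spacing])
    species_order = sorted(spec.n_per_leaflet)
    base_assignment = np.concatenate([
        np.full(spec.n_per_leaflet[s], s, dtype="U8") for s in species_order])
    assignments = {}
    for leaflet in ("upper", "lower"):
        if spec.arrangement == "mixed":
            assignments[leaflet] = base_assignment[rng.permutation(n_leaf)]
        else:
            assignments[leaflet] = base_assignment.copy()

    n_lipids = 2 * n_leaf
    n_ions = 2 * spec.n_per_leaflet.get(spec.counterion_species, 0)
    n_waters = int(round(spec.waters_per_lipid * n_lipids))

    # residue ids: lipids first (upper leaflet then lower), then ions, waters
    lipid_res = {}
    next_res = 1
    for leaflet in ("upper", "lower"):
        lipid_res[leaflet] = np.arange(next_res, next_res + n_leaf)
        next_res += n_leaf
    ion_res = np.arange(next_res, next_res + n_ions)
    next_res += n_ions
    water_res = np.arange(next_res, next_res + n_waters)

    frames = []
    for fi in range(spec.n_frames):
        res_idx, res_name, atm_name, coords = [], [], [], []
        for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
            assignment = assignments[leaflet]
            xy = sites + rng.normal(scale=spec.lateral_jitter,
                                    size=sites.shape) if spec.lateral_jitter > 0 \
                else sites.copy()
            z_p = center + sign * spec.d_p / 2.0 + rng.normal(
                scale=spec.z_sigma, size=n_leaf)
            for species in species_order:
                topo = topologies[species]
                members = np.flatnonzero(assignment == species)
                m = len(members)
                if m == 0:
                    continue
                p_pos = np.column_stack([xy[members], z_p[members]])
                names: list[str] = [topo.phosphorus_atom]
                blocks: list[np.ndarray] = [p_pos]
                if species in spec.head_tilt:
                    law = spec.head_tilt[species]
                    theta = law.sample(rng, m)
                    phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
                    head = p_pos + _HEAD_BOND_LENGTH * _unit_vectors(theta, phi, sign)
                    names.append(topo.head_vector_atoms[1])
                    blocks.append(head)
                if spec.include_chains:
                    tilt = spec.chain_tilt.get(species, 0.0)
                    phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
                    # rod pointing into the bilayer; the analysed director
                    # (terminal -> C1) then makes `tilt` with the outward normal
                    rod = -_unit_vectors(np.full(m, tilt), phi, sign)
                    for chain in (topo.sn1_chain, topo.sn2_chain):
                        for k, carbon in enumerate(chain):
                            pos_c = p_pos + (_CHAIN_OFFSET + k * _CHAIN_STEP) * rod
                            names.append(carbon)
                            blocks.append(pos_c)
                    carbon_pos = {name: block for name, block
                                  in zip(names, blocks)}
                    for site, s_target in spec.s_ch.get(species, {}).items():
                        if site not in carbon_pos:
                            raise ValueError(f"S_CH site {site!r} is not a "
                                             f"generated carbon of {species}")
                        theta_ch = math.degrees(ch_cone_angle(s_target))
                        for h_name in topologies[species].ch_bonds[site]:
                            phi_h = rng.uniform(0.0, 2.0 * np.pi, size=m)
                            h_pos = carbon_pos[site] + _CH_BOND_LENGTH * \
                                _unit_vectors(np.full(m, theta_ch), phi_h, 1.0)
                            names.append(h_name)
                            blocks.append(h_pos)
                per_lipid = np.stack(blocks, axis=1)        # (m, n_atoms, 3)
                coords.append(per_lipid.reshape(-1, 3))
                res_idx.append(np.repeat(lipid_res[leaflet][members], len(names)))
                res_name.append(np.full(m * len(names), species, dtype="U8"))
                atm_name.append(np.tile(np.array(names, dtype="U8"), m))
        if n_ions:
            half = n_ions // 2
            z_up = center + spec.d_p / 2.0 + spec.ion_z_offset + rng.normal(
                scale=spec.ion_z_sigma, size=half)
            z_lo = center - spec.d_p / 2.0 - spec.ion_z_offset + rng.normal(
                scale=spec.ion_z_sigma, size=n_ions - half)
            z_ion = np.concatenate([z_up, z_lo])
            xy_ion = rng.uniform(0.0, [lx, ly], size=(n_ions, 2))
            coords.append(np.column_stack([xy_ion, z_ion]))
            res_idx.append(ion_res)
            res_name.append(np.full(n_ions, "K", dtype="U8"))
            atm_name.append(np.full(n_ions, "K", dtype="U8"))
        if n_waters:
            slab = spec.water_pad - _WATER_GAP
            z_off = rng.uniform(0.0, slab, size=n_waters)
            side = rng.random(n_waters) < 0.5
            z_w = np.where(side, center + spec.d_p / 2.0 + _WATER_GAP + z_off,
                           center - spec.d_p / 2.0 - _WATER_GAP - z_off)
            xy_w = rng.uniform(0.0, [lx, ly], size=(n_waters, 2))
            coords.append(np.column_stack([xy_w, z_w]))
            res_idx.append(water_res)
            res_name.append(np.full(n_waters, "SOL", dtype="U8"))
            atm_name.append(np.full(n_waters, "MW", dtype="U8"))
        frames.append(Frame(np.concatenate(res_idx), np.concatenate(res_name),
                            np.concatenate(atm_name), np.vstack(coords), box,
                            time=float(fi)))

    uniform_apl = len(spec.n_per_leaflet) == 1
    truth = {
        "box": [lx, ly, lz],
        "n_lipids": n_lipids,
        "n_per_leaflet": dict(spec.n_per_leaflet),
        "x_anionic": spec.x_anionic,
        # Voronoi conservation fixes the mean cell area at cross-section / n;
        # with a shared lattice every species shares the lattice mean APL.
        "apl": {s: (spec.apl[s] if uniform_apl else spec.mean_apl)
                for s in spec.n_per_leaflet},
        "d_p": spec.d_p,
        "head_tilt_mean": {s: law.angle_deg for s, law in spec.head_tilt.items()},
        "chain_tilt": dict(spec.chain_tilt),
        "s_ch": {s: dict(sites) for s, sites in spec.s_ch.items()},
        "n_frames": spec.n_frames,
        "seed": spec.seed,
    }
    return frames, truth


def write_bilayer(spec: BilayerSpec, out_dir,
                  topologies: Mapping[str, LipidTopology] | None = None,
                  ) -> tuple[Path, Path]:
    """Generate a trajectory and write it as multi-frame GRO + JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, truth = generate_bilayer(spec, topologies)
    traj_path = out / "trajectory.gro"
    truth_path = out / "ground_truth.json"
    write_trajectory(frames, traj_path)
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return traj_path, truth_path


# ---------------------------------------------------------------------------
# isotherm families


@dataclass
class IsothermSpec:
    """Exponential isotherm family with a constant excess-area term.

    Each pure component follows A(pi) = A0 exp(-pi / K), whose compression
    modulus is exactly K everywhere.  A mixture at POPS mole fraction x2 is
    the ideal combination of the pure curves plus the constant excess area
    ``excess_area[x2]`` (nm^2), for which the excess free energy at pi* has
    the closed form 0.6022 * a * pi*.
    """

    a0: tuple[float, float] = (0.90, 0.85)     # nm^2 at pi = 0 (comp 1, comp 2)
    k: tuple[float, float] = (81.0, 56.0)      # mN/m
    compositions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    excess_area: dict[float, float] = field(default_factory=dict)
    pi_max: float = 45.0
    n_points: int = 200
    noise_sigma: float = 0.0                   # nm^2 on sampled areas
    pi_star: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k) <= 0 or min(self.a0) <= 0:
            raise ValueError("A0 and K must be positive")
        if self.pi_max <= 0 or self.n_points < 4:
            raise ValueError("need a positive pressure range and >= 4 points")
        if self.pi_star > self.pi_max:
            raise ValueError("pi_star must lie inside the sampled range")


def generate_isotherms(spec: IsothermSpec) -> tuple[dict[float, Isotherm], dict]:
    """Sample the isotherm family; return records keyed by x2 plus truth.

    The truth record carries the closed-form compression-modulus curve (on
    the sampled pressure grid), its maximum, and the analytic excess free
    energy at pi* for every composition.
    """
    rng = np.random.default_rng(spec.seed)
    pi = np.linspace(0.0, spec.pi_max, spec.n_points)
    a1 = spec.a0[0] * np.exp(-pi / spec.k[0])
    a2 = spec.a0[1] * np.exp(-pi / spec.k[1])
    da1 = -a1 / spec.k[0]
    da2 = -a2 / spec.k[1]
    isotherms: dict[float, Isotherm] = {}
    truth = {"pi_star": spec.pi_star, "cs_inverse_max": {}, "dg_excess": {},
             "cs_inverse": {}, "pi": pi.tolist()}
    for x2 in spec.compositions:
        x1 = 1.0 - x2
        a_exc = spec.excess_area.get(x2, 0.0)
        if x2 in (0.0, 1.0) and a_exc:
            raise ValueError("pure components cannot carry excess area")
        area = x1 * a1 + x2 * a2 + a_exc
        if np.any(np.diff(area) >= 0):
            raise ValueError("family is not strictly decreasing in area")
        darea = x1 * da1 + x2 * da2
        cs = -area / darea
        sampled = area if spec.noise_sigma == 0 else \
            area + rng.normal(scale=spec.noise_sigma, size=area.shape)
        isotherms[x2] = Isotherm(pi.copy(), sampled, x1=x1, x2=x2,
                                 label=f"x2={x2:g}")
        truth["cs_inverse"][x2] = cs.tolist()
        truth["cs_inverse_max"][x2] = float(cs.max())
        truth["dg_excess"][x2] = KJ_PER_MOL_PER_MN_NM * a_exc * spec.pi_star
    return isotherms, truth
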