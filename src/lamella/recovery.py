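"""Parameter-recovery protocols: generator -> analysis -> estimate.

Each function builds synthetic data whose ground truth is set by the caller
(typically a published reference value), runs the corresponding analysis and
returns the recovered estimate with its seed-to-seed standard error.  These
protocols are the package's verification backbone: they demonstrate that
every analysis stage recovers known inputs under realistic noise.

Sizes default to the study conditions the analyses target (100 lipids per
leaflet, 100 independent frames, 20 seeds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Box, Frame
from .monolayer import compression_modulus, excess_free_energy
from .structure import (bilayer_thickness, contact_counts, order_parameters,
                        tilt_distribution, voronoi_apl)
from .synthetic import BilayerSpec, IsothermSpec, TiltLaw, generate_bilayer, generate_isotherms
from .topology import default_topologies

__all__ = [
    "RecoveryResult",
    "recover_thickness",
    "recover_apl",
    "recover_head_tilt",
    "recover_cs_max",
    "recover_dg_excess",
    "recover_s_ch_plateau",
    "lattice_contact_count",
]


@dataclass(frozen=True)
class RecoveryResult:
    """Recovered estimate, its standard error over seeds, and problem size."""

    value: float
    stderr: float
    n: int


def _seed_list(base_seed: int, n_seeds: int) -> list[int]:
    # independent child seeds, kept below 2**31
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n_seeds)]


def _aggregate(values: list[float], n: int) -> RecoveryResult:
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return RecoveryResult(float(arr.mean()), se, n)


def recover_thickness(d_p: float, n_per_leaflet: int = 100, n_frames: int = 100,
                      z_sigma: float = 0.1, n_seeds: int = 20,
                      seed: int = 0) -> RecoveryResult:
    """Recover a configured phosphorus-plane separation from noisy planes."""
    topos = default_topologies()
    values = []
    for s in _seed_list(seed, n_seeds):
        spec = BilayerSpec(n_per_leaflet={"POPC": n_per_leaflet},
                           apl={"POPC": 0.634}, d_p=d_p, z_sigma=z_sigma,
                           n_frames=n_frames, waters_per_lipid=0.0,
                           include_chains=False, seed=s)
        frames, _ = generate_bilayer(spec, topos)
        values.append(bilayer_thickness(frames, {"POPC": topos["POPC"]}).mean)
    return _aggregate(values, n_per_leaflet * 2 * n_frames * n_seeds)


def recover_apl(apl: float, species: str = "POPC", n_per_leaflet: int = 100,
                n_frames: int = 100, jitter: float = 0.05, n_seeds: int = 20,
                seed: int = 0) -> RecoveryResult:
    """Recover a configured area per lipid from a jittered pure bilayer."""
    topos = default_topologies()
    values = []
    for s in _seed_list(seed, n_seeds):
        spec = BilayerSpec(n_per_leaflet={species: n_per_leaflet},
                           apl={species: apl}, d_p=4.0,
                           lateral_jitter=jitter, n_frames=n_frames,
                           waters_per_lipid=0.0, include_chains=False, seed=s)
        frames, _ = generate_bilayer(spec, topos)
        result = voronoi_apl(frames, {species: topos[species]})
        values.append(result.per_species[species])
    return _aggregate(values, n_per_leaflet * 2 * n_frames * n_seeds)


def recover_head_tilt(angle_deg: float, species: str = "POPC",
                      n_lipids: int = 10_000, n_seeds: int = 20,
                      seed: int = 0) -> RecoveryResult:
    """Recover a fixed-cone headgroup tilt from uniform-azimuth vectors."""
    topos = default_topologies()
    values = []
    for s in _seed_list(seed, n_seeds):
        spec = BilayerSpec(n_per_leaflet={species: n_lipids // 2},
                           apl={species: 0.6}, d_p=4.0,
                           head_tilt={species: TiltLaw(angle_deg)},
                           n_frames=1, waters_per_lipid=0.0,
                           include_chains=False, seed=s)
        frames, _ = generate_bilayer(spec, topos)
        dist = tilt_distribution(frames, topos[species], "head",
                                 leaflet_topologies={species: topos[species]})
        values.append(dist.mean)
    return _aggregate(values, n_lipids * n_seeds)


def recover_cs_max(k_pure: float, n_points: int = 200) -> RecoveryResult:
    """Recover the compression-modulus maximum of an exponential isotherm
    constructed with closed-form Cs^-1 = K everywhere."""
    spec = IsothermSpec(a0=(0.90, 0.85), k=(k_pure, k_pure),
                        compositions=(0.0, 1.0), n_points=n_points, seed=0)
    isotherms, _ = generate_isotherms(spec)
    curve = compression_modulus(isotherms[0.0])
    return RecoveryResult(curve.max_value, 0.0, n_points)


def recover_dg_excess(dg_target: float, pi_star: float = 30.0,
                      n_points: int = 200) -> RecoveryResult:
    """Recover an excess free energy from a constant-excess-area family with
    closed-form dG^exc = 0.6022 * a * pi*."""
    a_exc = dg_target / (pi_star * 0.6022)
    spec = IsothermSpec(compositions=(0.0, 0.5, 1.0),
                        excess_area={0.5: a_exc}, n_points=n_points,
                        pi_star=pi_star, seed=0)
    isotherms, _ = generate_isotherms(spec)
    dg = excess_free_energy(isotherms[0.5], isotherms[0.0], isotherms[1.0],
                            pi_star)
    return RecoveryResult(dg, 0.0, n_points)


def recover_s_ch_plateau(s_target: float, n_per_leaflet: int = 50,
                         n_frames: int = 10, seed: int = 0) -> RecoveryResult:
    """Recover |S_CH| from C-H vectors on the cone encoding ``s_target``."""
    topos = default_topologies()
    spec = BilayerSpec(n_per_leaflet={"POPC": n_per_leaflet},
                       apl={"POPC": 0.634}, d_p=4.0,
                       s_ch={"POPC": {"C32": s_target}}, n_frames=n_frames,
                       waters_per_lipid=0.0, seed=seed)
    frames, _ = generate_bilayer(spec, topos)
    profile = order_parameters(frames, topos["POPC"], sites=["C32"])
    return RecoveryResult(float(profile.s_ch_abs[0]), float(profile.stderr[0]),
                          n_per_leaflet * 2 * n_frames)


def lattice_contact_frame(n_side: int = 4, spacing: float = 0.8,
                          arm: float = 0.25) -> Frame:
    """Periodic square lattice of 5-atom lipids whose atoms approach only
    the four nearest lattice neighbours within 0.6 nm."""
    records_res, records_name, coords = [], [], []
    res = 1
    for i in range(n_side):
        for j in range(n_side):
            c = np.array([spacing / 2 + spacing * i,
                          spacing / 2 + spacing * j, 2.5])
            offsets = [np.zeros(3), [arm, 0, 0], [-arm, 0, 0],
                       [0, arm, 0], [0, -arm, 0]]
            for off in offsets:
                records_res.append(res)
                records_name.append("C1")
                coords.append(c + np.asarray(off, dtype=float))
            res += 1
    n = len(records_res)
    return Frame(records_res, ["POPC"] * n, records_name,
                 np.array(coords), Box(np.array([n_side * spacing,
                                                 n_side * spacing, 5.0])))


def lattice_contact_count(cutoff: float = 0.6) -> RecoveryResult:
    """Contacts per lipid on the deterministic 4-neighbour lattice."""
    frame = lattice_contact_frame()
    summary = contact_counts([frame], [("POPC", None)], [("POPC", None)],
                             cutoff=cutoff)
    return RecoveryResult(summary.mean_contacts_per_a, 0.0, frame.n_atoms)
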