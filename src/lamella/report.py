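"""Analysis orchestration and tabular report generation.

`run_bilayer_analysis` executes every structural observable on a trajectory
and writes one TSV per observable plus a summary table (per-species APL and
d_P); `run_monolayer_analysis` runs the full isotherm pipeline over a
composition series.  Reports are deterministic: identical inputs and
configuration give byte-identical files.  Every file starts with header
comments naming the package version and the configuration values used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .io import read_trajectory
from .monolayer import (Isotherm, classify_state, compression_modulus,
                        mixing_analysis)
from .structure import (bilayer_thickness, contact_counts, density_profile,
                        lateral_rdf, like_lipid_clusters, order_parameters,
                        tilt_distribution, voronoi_apl)
from .topology import LipidTopology, default_topologies, load_topologies

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "StageError", "run_bilayer_analysis",
           "run_monolayer_analysis"]


class StageError(RuntimeError):
    """Failure inside one analysis stage; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage}: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Configuration of a bilayer analysis run."""

    trajectory: str
    out_dir: str
    topology_yaml: str | None = None
    burn_in: int = 0
    contact_cutoff: float = 0.6        # nm
    tilt_bin_width: float = 1.0        # degrees
    density_bin_width: float = 0.1     # nm
    rdf_bin_width: float = 0.05        # nm
    pi_star: float = 30.0              # mN/m (monolayer workflow)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "tilt_bin_width", "density_bin_width",
                     "rdf_bin_width", "pi_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")

    def header(self) -> str:
        pairs = ", ".join(f"{k}={v}" for k, v in sorted(vars(self).items()))
        return f"# lamella {__version__}\n# config: {pairs}\n"


def _write_tsv(df: pd.DataFrame, path: Path, header: str,
               written: list[Path]) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    written.append(path)


def run_bilayer_analysis(config: AnalysisConfig,
                         topologies: Mapping[str, LipidTopology] | None = None,
                         ) -> dict[str, Path]:
    """Run all structural observables; return the written report files.

    On any stage failure every partially written output is removed and a
    :class:`StageError` naming the stage is raised.
    """
    if topologies is None:
        topologies = (load_topologies(config.topology_yaml)
                      if config.topology_yaml else default_topologies())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header()
    written: list[Path] = []
    try:
        try:
            frames = read_trajectory(config.trajectory, burn_in=config.burn_in)
            if not frames:
                raise ValueError("no frames left after burn-in")
        except Exception as exc:
            raise StageError("read_trajectory", exc) from exc

        present = [s for s in topologies
                   if frames[0].select(s).any()]
        if not present:
            raise StageError("species_detection",
                             ValueError("no known lipid species in trajectory"))

        try:
            apl = voronoi_apl(frames, {s: topologies[s] for s in present})
            d_p = bilayer_thickness(frames, {s: topologies[s] for s in present})
        except Exception as exc:
            raise StageError("voronoi_apl/bilayer_thickness", exc) from exc
        summary = pd.DataFrame(
            [{"species": s, "apl_nm2": apl.per_species[s],
              "apl_sd_nm2": apl.per_species_sd[s],
              "d_p_nm": d_p.mean, "d_p_sd_nm": d_p.sd} for s in present])
        _write_tsv(summary, out / "summary.tsv", header, written)
        _write_tsv(apl.breakdown, out / "apl_breakdown.tsv", header, written)

        lipid_topos = {s: topologies[s] for s in present}
        for species in present:
            topo = topologies[species]
            try:
                for kind in ("head", "sn1"):
                    dist = tilt_distribution(frames, topo, kind,
                                             bin_width=config.tilt_bin_width,
                                             leaflet_topologies=lipid_topos)
                    df = pd.DataFrame({"angle_deg": dist.bin_centers,
                                       "probability": dist.probability})
                    extra = (f"# mean_deg: {dist.mean:.6g}\n"
                             f"# mode_deg: {dist.mode:.6g}\n")
                    _write_tsv(df, out / f"tilt_{kind}_{species}.tsv",
                               header + extra, written)
            except Exception as exc:
                raise StageError(f"tilt_distribution[{species}]", exc) from exc
            try:
                frame0 = frames[0]
                has_h = any(frame0.select(species, h).any()
                            for hs in topo.ch_bonds.values() for h in hs)
                if has_h:
                    sites = [c for c in topo.sn1_chain
                             if topo.ch_bonds.get(c)
                             and frame0.select(species, c).any()
                             and all(frame0.select(species, h).any()
                                     for h in topo.ch_bonds[c])]
                    if sites:
                        prof = order_parameters(frames, topo, sites=sites)
                        _write_tsv(prof.to_frame(),
                                   out / f"order_parameters_{species}.tsv",
                                   header, written)
            except Exception as exc:
                raise StageError(f"order_parameters[{species}]", exc) from exc
            try:
                stats = like_lipid_clusters(frames[0], lipid_topos, species,
                                            cutoff=config.contact_cutoff)
                df = pd.DataFrame(sorted(stats.size_histogram.items()),
                                  columns=["cluster_size", "count"])
                _write_tsv(df, out / f"clusters_{species}.tsv",
                           header + f"# mean_size: {stats.mean_size:.6g}\n",
                           written)
            except Exception as exc:
                raise StageError(f"like_lipid_clusters[{species}]", exc) from exc

        try:
            rows = []
            for a in present:
                for b in present:
                    if b < a:
                        continue
                    summary_c = contact_counts(frames, [(a, None)], [(b, None)],
                                               cutoff=config.contact_cutoff,
                                               pair_label=f"{a}-{b}")
                    rows.append({"pair": summary_c.pair_label,
                                 "contacts_per_molecule": summary_c.mean_contacts_per_a,
                                 "cutoff_nm": summary_c.cutoff})
            _write_tsv(pd.DataFrame(rows), out / "contacts.tsv", header, written)
        except Exception as exc:
            raise StageError("contact_counts", exc) from exc

        try:
            groups = [("P_" + s, [(s, topologies[s].phosphorus_atom)])
                      for s in present]
            if frames[0].select("SOL").any():
                groups.append(("water", [("SOL", None)]))
            if frames[0].select("K").any():
                groups.append(("K", [("K", None)]))
            for label, selection in groups:
                prof = density_profile(frames, selection, lipid_topos,
                                       bin_width=config.density_bin_width,
                                       label=label)
                df = pd.DataFrame({"z_nm": prof.bin_centers,
                                   "density_kg_m3": prof.density})
                _write_tsv(df, out / f"density_{label}.tsv", header, written)
        except Exception as exc:
            raise StageError("density_profile", exc) from exc

        if len(present) >= 2:
            try:
                rdf = lateral_rdf(frames, lipid_topos, present[0], present[1],
                                  bin_width=config.rdf_bin_width)
                df = pd.DataFrame({"r_nm": rdf.bin_centers, "g_r": rdf.g,
                                   "cumulative_n": rdf.cumulative})
                _write_tsv(df, out / f"rdf_{rdf.pair_label}.tsv", header, written)
            except Exception as exc:
                raise StageError("lateral_rdf", exc) from exc
    except StageError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return {p.stem: p for p in written}


def run_monolayer_analysis(isotherms: Mapping[float, Isotherm], out_dir,
                           pi_star: float = 30.0,
                           header_extra: str = "") -> dict[str, Path]:
    """Isotherm workflow over a composition series keyed by x2.

    Requires both pure components (x2 = 0 and 1) — the ideal-mixing
    reference and the excess free energy are undefined without them — and at
    least one mixture.
    """
    compositions = sorted(isotherms)
    if 0.0 not in isotherms or 1.0 not in isotherms:
        raise ValueError("both pure-component isotherms (x2 = 0 and x2 = 1) "
                         "are required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# lamella {__version__}\n# pi_star: {pi_star}\n" + header_extra)
    written: list[Path] = []

    cs_rows = []
    curve_frames = []
    for x2 in compositions:
        curve = compression_modulus(isotherms[x2])
        cs_rows.append({"x2": x2, "cs_inv_max_mN_per_m": curve.max_value,
                        "pi_at_max_mN_per_m": curve.pi_at_max,
                        "state": classify_state(curve.max_value)})
        df = curve.to_frame()
        df.insert(0, "x2", x2)
        curve_frames.append(df)
    _write_tsv(pd.DataFrame(cs_rows), out / "compression_modulus_max.tsv",
               header, written)
    _write_tsv(pd.concat(curve_frames, ignore_index=True),
               out / "compression_modulus_curves.tsv", header, written)

    pure1, pure2 = isotherms[0.0], isotherms[1.0]
    mix_rows = []
    for x2 in compositions:
        mix = mixing_analysis(isotherms[x2], pure1, pure2, pi_star=pi_star)
        mix_rows.append({"x2": x2, "a12_nm2": mix.a12,
                         "ideal_area_nm2": mix.ideal_area,
                         "excess_area_nm2": mix.excess_area,
                         "dg_excess_kJ_mol": mix.dg_excess,
                         "note": mix.annotation})
    _write_tsv(pd.DataFrame(mix_rows), out / "mixing_analysis.tsv",
               header, written)
    return {p.stem: p for p in written}
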