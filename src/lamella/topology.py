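"""Lipid species topologies: atom-name conventions for each analysis.

A :class:`LipidTopology` names, for one lipid species, the atoms that the
structural observables need: the phosphorus atom, the two atoms spanning the
headgroup vector, the ordered carbon lists of the two acyl chains and the
hydrogens attached to each carbon.  Defaults follow the CHARMM36 all-atom
naming scheme; any of them can be overridden from a YAML file for systems
built with a different force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "LipidTopology",
    "default_topologies",
    "load_topologies",
    "HEADGROUP_SITES",
]


@dataclass(frozen=True)
class LipidTopology:
    """Atom-name conventions for one lipid species.

    Parameters
    ----------
    species_name
        Residue name identifying the species (e.g. ``POPC``).
    head_vector_atoms
        Pair of atom names spanning the headgroup tilt vector, tail first
        (P -> N for phosphatidylcholine, P -> serine alpha-carbon for
        phosphatidylserine).
    sn1_chain, sn2_chain
        Ordered carbon atom names along each acyl chain, glycerol end first.
    ch_bonds
        Map from carbon atom name to the names of its attached hydrogens.
    phosphorus_atom
        Name of the headgroup phosphorus atom.
    """

    species_name: str
    head_vector_atoms: tuple[str, str]
    sn1_chain: tuple[str, ...]
    sn2_chain: tuple[str, ...]
    ch_bonds: dict[str, tuple[str, ...]] = field(default_factory=dict)
    phosphorus_atom: str = "P"

    def __post_init__(self) -> None:
        if not self.species_name:
            raise ValueError("species_name must be non-empty")
        if self.head_vector_atoms[0] == self.head_vector_atoms[1]:
            raise ValueError("head_vector_atoms must be distinct")
        for label, chain in (("sn1", self.sn1_chain), ("sn2", self.sn2_chain)):
            if not chain:
                raise ValueError(f"{label}_chain must be non-empty")
            if len(set(chain)) != len(chain):
                raise ValueError(f"{label}_chain contains duplicate atom names")


def _chain(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(1, n + 1))


def _chain_hydrogens(chain: tuple[str, ...], suffixes=("X", "Y")) -> dict[str, tuple[str, ...]]:
    # CHARMM chain hydrogens are named after the carbon index (C32 -> H2X, H2Y).
    out: dict[str, tuple[str, ...]] = {}
    for name in chain:
        idx = name[2:]
        out[name] = tuple(f"H{idx}{s}" for s in suffixes)
    return out


#: NMR-style headgroup/glycerol site labels mapped to CHARMM carbon names.
HEADGROUP_SITES: dict[str, str] = {
    "alpha": "C11",
    "beta": "C12",
    "g1": "C3",
    "g2": "C2",
    "g3": "C1",
}


def default_topologies() -> dict[str, LipidTopology]:
    """CHARMM36 conventions for POPC and POPS.

    For POPC the headgroup vector runs from the phosphorus to the choline
    nitrogen; for POPS it runs from the phosphorus to the serine carbon
    bonded to the ammonium group (C12 in CHARMM naming).  The sn-1
    (palmitoyl, C31-C316) and sn-2 (oleoyl, C21-C218) chains are shared by
    both species.
    """
    sn1 = _chain("C3", 16)
    sn2 = _chain("C2", 18)
    ch = _chain_hydrogens(sn1)
    ch.update(_chain_hydrogens(sn2, suffixes=("R", "S")))
    # glycerol and headgroup carbons carry two hydrogens apiece except g2
    ch.update({"C1": ("HA", "HB"), "C2": ("HS",), "C3": ("HX", "HY"),
               "C11": ("H11A", "H11B"), "C12": ("H12A", "H12B")})
    return {
        "POPC": LipidTopology(
            species_name="POPC",
            head_vector_atoms=("P", "N"),
            sn1_chain=sn1,
            sn2_chain=sn2,
            ch_bonds=dict(ch),
        ),
        "POPS": LipidTopology(
            species_name="POPS",
            head_vector_atoms=("P", "C12"),
            sn1_chain=sn1,
            sn2_chain=sn2,
            ch_bonds=dict(ch),
        ),
    }


def load_topologies(path) -> dict[str, LipidTopology]:
    """Read topology overrides from YAML, merged over the defaults.

    The file maps species name to any subset of the LipidTopology fields::

        POPS:
          head_vector_atoms: [P, N]
    """
    topos = default_topologies()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for species, fields in raw.items():
        base = topos.get(species)
        kwargs = {
            "species_name": species,
            "head_vector_atoms": tuple(base.head_vector_atoms) if base else ("P", "N"),
            "sn1_chain": tuple(base.sn1_chain) if base else (),
            "sn2_chain": tuple(base.sn2_chain) if base else (),
            "ch_bonds": dict(base.ch_bonds) if base else {},
            "phosphorus_atom": base.phosphorus_atom if base else "P",
        }
        for key, value in (fields or {}).items():
            if key == "head_vector_atoms":
                kwargs[key] = tuple(value)
            elif key in ("sn1_chain", "sn2_chain"):
                kwargs[key] = tuple(value)
            elif key == "ch_bonds":
                kwargs[key] = {k: tuple(v) for k, v in value.items()}
            elif key == "phosphorus_atom":
                kwargs[key] = str(value)
            else:
                raise KeyError(f"unknown LipidTopology field {key!r} for {species}")
        topos[species] = LipidTopology(**kwargs)
    return topos
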