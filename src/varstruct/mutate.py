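"""Point-mutant construction by rigid-backbone side-chain replacement.

The mutant keeps every backbone atom (N, CA, C, O) of every residue
bitwise unchanged; the side chain at the mutated position is rebuilt from
idealized internal coordinates, choosing among a compact discrete rotamer
library the chi combination with the lowest steric clash score against the
rest of the structure.  Ties go to the rotamer with the higher prior
weight, then to library order.  There is no continuous minimization and no
relaxation of neighbouring side chains, so all structural differences in a
mutant are confined to the substituted side chain; this is the main
divergence from restraint-based mutant modelling and the reason
interaction diffs are compared at the level of detected pairs, not exact
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Atom, ProteinStructure, Residue, VariantSpec, VarstructError
from .data.chemistry import element_of, vdw_radius
from .data.sidechains import (ANGLE_N_CA_CB, BOND_CA_CB, LIBRARY_VERSION,
                              ROTAMERS, SIDECHAIN_ZMATRIX, TORSION_C_N_CA_CB)
from .geometry import place_atom


@dataclass(frozen=True)
class RotamerLibrary:
    """Backbone-independent chi-angle library with prior weights."""

    rotamers: dict[str, list[tuple[tuple[float, ...], float]]]
    version: str = LIBRARY_VERSION

    def for_type(self, aa: str) -> list[tuple[tuple[float, ...], float]]:
        if aa not in self.rotamers:
            raise VarstructError(f"no rotamers for residue type {aa!r}")
        return self.rotamers[aa]


DEFAULT_LIBRARY = RotamerLibrary(ROTAMERS)

# Ideal-geometry side chains carry small 1-4 overlaps against their own
# backbone (up to ~2.7 for the proline ring) even with nothing nearby;
# only scores clearly above that baseline indicate a real steric conflict.
STRAINED_THRESHOLD = 3.0


def build_sidechain(res_n: np.ndarray, res_ca: np.ndarray, res_c: np.ndarray,
                    aa: str, chis: tuple[float, ...]) -> list[Atom]:
    """Idealized side-chain heavy atoms for one residue given its backbone
    frame and chi angles.  Gly gives no atoms; everything else starts at CB."""
    if aa == "G":
        return []
    cb = place_atom(res_c, res_n, res_ca, BOND_CA_CB, ANGLE_N_CA_CB,
                    TORSION_C_N_CA_CB)
    coords = {"N": res_n, "CA": res_ca, "C": res_c, "CB": cb}
    atoms = [Atom("CB", "C", cb)]
    chi_map = {f"chi{k + 1}": chis[k] for k in range(len(chis))}
    for name, (r1, r2, r3), bond, ang, tors in SIDECHAIN_ZMATRIX[aa]:
        if isinstance(tors, tuple):
            chi_name, offset = tors
            if chi_name not in chi_map:
                raise VarstructError(
                    f"{aa}: rotamer provides no {chi_name} for atom {name}")
            torsion = chi_map[chi_name] + offset
        else:
            torsion = float(tors)
        pos = place_atom(coords[r1], coords[r2], coords[r3], bond, ang, torsion)
        coords[name] = pos
        atoms.append(Atom(name, element_of(name), pos))
    return atoms


def _bonded_exclusions(aa: str) -> set[tuple[str, str]]:
    """Side-chain/backbone atom pairs within 2 covalent bonds (1-2 and 1-3),
    excluded from the clash score."""
    pairs = {("CB", "CA"), ("CB", "N"), ("CB", "C")}
    for name, (_, _, r3), *_ in SIDECHAIN_ZMATRIX.get(aa, []):
        if r3 in ("N", "CA", "C"):
            pairs.add((name, r3))
        # 1-3 via CA for gamma atoms bonded to CB
        if r3 == "CB":
            pairs.add((name, "CA"))
    if aa == "P":  # ring closure: CD is bonded to N
        pairs.update({("CD", "N"), ("CG", "N"), ("CD", "CA")})
    return pairs


def clash_score_atoms(side_atoms: list[Atom], env_coords: np.ndarray,
                      env_radii: np.ndarray, env_names: list[str] | None = None,
                      exclusions: set[tuple[str, str]] | None = None,
                      env_is_own_backbone: np.ndarray | None = None) -> float:
    """Sum over non-bonded atom pairs of max(0, r_vdw_sum - d)^2."""
    score = 0.0
    for at in side_atoms:
        r1 = vdw_radius(at.element)
        d = np.linalg.norm(env_coords - at.coords, axis=1)
        overlap = np.maximum(0.0, (env_radii + r1) - d)
        if exclusions and env_names is not None and env_is_own_backbone is not None:
            for k, name in enumerate(env_names):
                if env_is_own_backbone[k] and (at.name, name) in exclusions:
                    overlap[k] = 0.0
        score += float(np.sum(overlap ** 2))
    return score


def clash_score(structure: ProteinStructure, position: int) -> float:
    """Steric clash of the side chain at `position` against the rest of the
    structure (own backbone included, 1-2/1-3 bonded pairs excluded)."""
    res = structure.residue_at(position)
    side = res.sidechain
    if not side:
        return 0.0
    env, names, own = [], [], []
    for r in structure.residues:
        for a in r.atoms:
            if r is res and not a.is_backbone:
                continue
            env.append(a)
            names.append(a.name)
            own.append(r is res)
    env_coords = np.array([a.coords for a in env])
    env_radii = np.array([vdw_radius(a.element) for a in env])
    return clash_score_atoms(side, env_coords, env_radii, names,
                             _bonded_exclusions(res.aa), np.array(own))


def build_mutant(structure: ProteinStructure, variant: VariantSpec,
                 seed: int = 0, library: RotamerLibrary = DEFAULT_LIBRARY
                 ) -> tuple[ProteinStructure, dict]:
    """Build the point-mutant model of one missense variant.

    Returns (mutant structure, info dict with chosen rotamer, clash score
    and a 'strained' flag set when no clash-free rotamer exists).  The
    `seed` argument is accepted for interface stability; the default
    builder is fully deterministic and does not use it.
    """
    res = None
    for r in structure.residues:
        if r.number == variant.position:
            res = r
            break
    if res is None:
        raise VarstructError(f"no residue at position {variant.position}")
    if res.aa != variant.wt_aa:
        raise VarstructError(
            f"variant {variant.label}: structure has {res.aa} at "
            f"position {variant.position}")

    mutant = structure.copy()
    mres = mutant.residue_at(variant.position)
    backbone = {a.name: a for a in mres.atoms if a.is_backbone}
    for name in ("N", "CA", "C"):
        if name not in backbone:
            raise VarstructError(
                f"position {variant.position}: backbone incomplete, cannot mutate")
    n, ca, c = (backbone[x].coords for x in ("N", "CA", "C"))

    # environment for clash scoring: everything except the old side chain
    env = []
    for r in mutant.residues:
        for a in r.atoms:
            if r is mres and not a.is_backbone:
                continue
            env.append((a, r is mres))
    env_coords = np.array([a.coords for a, _ in env])
    env_radii = np.array([vdw_radius(a.element) for a, _ in env])
    env_names = [a.name for a, _ in env]
    env_own = np.array([own for _, own in env])
    exclusions = _bonded_exclusions(variant.mut_aa)

    best = None  # (score, -weight, index, atoms)
    for idx, (chis, weight) in enumerate(library.for_type(variant.mut_aa)):
        atoms = build_sidechain(n, ca, c, variant.mut_aa, chis)
        score = clash_score_atoms(atoms, env_coords, env_radii, env_names,
                                  exclusions, env_own)
        key = (round(score, 6), -weight, idx)
        if best is None or key < best[0]:
            best = (key, atoms, chis)
    assert best is not None
    (score, _, idx), atoms, chis = best

    mres.atoms = [a for a in mres.atoms if a.is_backbone] + atoms
    mres.aa = variant.mut_aa
    mutant.source = f"{structure.source}|{variant.label}"
    info = {
        "variant": variant.label,
        "rotamer_index": idx,
        "chis": list(chis),
        "clash_score": float(score),
        "strained": bool(score > STRAINED_THRESHOLD),
        "library_version": library.version,
        "seed": seed,
    }
    return mutant, info
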