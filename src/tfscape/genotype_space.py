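"""Joint TF-RE sequence space and the encoded design matrices.

The space is the full factorial of 8 recognition-helix (RH) protein variants
(three two-state sites: 25 glu/GLY, 26 gly/SER, 29 ala/VAL; lower case =
ancestral, upper case = derived) with 16 response-element (RE) half-site
variants (nucleotides at the two variable half-site positions 3 and 4) —
128 joint genotypes in all.

Two encodings of this space are provided for regression modelling:

* ``abc_wyk`` — each protein site is a single ±1 coordinate (ancestral −1,
  derived +1); each RE site is the tetrahedral WYK embedding of its
  nucleotide as a ±1 three-vector.  Interaction columns are products of
  their factor coordinates.  On the complete balanced factorial all columns
  are mutually orthogonal, so the intercept is the grand mean and every
  coefficient is a mean-centred contrast.
* ``binary`` — one indicator column per genetic state (1 if present, else
  0), with product indicators for state combinations.  This design is
  deliberately overcomplete (one-hot columns sum to 1) and is used to
  cross-validate effects estimated under the tetrahedral encoding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NUCLEOTIDES",
    "PROTEIN_SITES",
    "RESIDUES",
    "WYK",
    "ProteinGenotype",
    "REGenotype",
    "JointGenotype",
    "Move",
    "ModelSpec",
    "ANCSR1",
    "ERE",
    "SRE1",
    "SRE2",
    "enumerate_protein_genotypes",
    "enumerate_re_genotypes",
    "enumerate_joint_genotypes",
    "wyk_encode",
    "abc_encode",
    "binary_encode",
    "build_design_matrix",
    "neighbors",
    "apply_move",
    "probe_sequence",
]

NUCLEOTIDES = ("A", "C", "G", "T")

#: RH site numbering and (ancestral, derived) residue names.
PROTEIN_SITES = (25, 26, 29)
RESIDUES = {25: ("glu", "GLY"), 26: ("gly", "SER"), 29: ("ala", "VAL")}

#: Tetrahedral WYK embedding of the four nucleotides.
WYK = {
    "A": (1, -1, -1),
    "C": (-1, 1, -1),
    "G": (-1, -1, 1),
    "T": (1, 1, 1),
}

_PROBE_PREFIX = "CCAG"
_PROBE_SUFFIX = "CA"


class UnknownGenotypeError(ValueError):
    """A genotype label does not belong to the supported sequence space."""


@dataclass(frozen=True, order=True)
class ProteinGenotype:
    """An RH variant: derived-state flags at sites 25, 26 and 29."""

    derived25: bool
    derived26: bool
    derived29: bool

    @property
    def states(self) -> tuple[bool, bool, bool]:
        return (self.derived25, self.derived26, self.derived29)

    @property
    def hamming(self) -> int:
        """Number of derived states (distance to the all-ancestral RH)."""
        return sum(self.states)

    @property
    def label(self) -> str:
        parts = [
            RESIDUES[site][flag]
            for site, flag in zip(PROTEIN_SITES, self.states)
        ]
        return "-".join(parts)

    def residue(self, site: int) -> str:
        return RESIDUES[site][self.states[PROTEIN_SITES.index(site)]]

    @classmethod
    def from_label(cls, label: str) -> "ProteinGenotype":
        parts = label.split("-")
        if len(parts) != 3:
            raise UnknownGenotypeError(f"bad protein label {label!r}")
        flags = []
        for site, part in zip(PROTEIN_SITES, parts):
            anc, der = RESIDUES[site]
            if part == anc:
                flags.append(False)
            elif part == der:
                flags.append(True)
            else:
                raise UnknownGenotypeError(
                    f"bad residue {part!r} at site {site} in {label!r}"
                )
        return cls(*flags)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True, order=True)
class REGenotype:
    """An RE half-site variant: nucleotides at positions 3 and 4."""

    n3: str
    n4: str

    def __post_init__(self) -> None:
        for n in (self.n3, self.n4):
            if n not in NUCLEOTIDES:
                raise UnknownGenotypeError(f"invalid nucleotide {n!r}")

    @property
    def label(self) -> str:
        return self.n3 + self.n4

    @classmethod
    def from_label(cls, label: str) -> "REGenotype":
        if len(label) != 2:
            raise UnknownGenotypeError(f"bad RE label {label!r}")
        return cls(label[0], label[1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True, order=True)
class JointGenotype:
    """One TF:RE complex — a point in the 8 x 16 joint space."""

    protein: ProteinGenotype
    re: REGenotype

    @property
    def label(self) -> str:
        return f"{self.protein.label}:{self.re.label}"

    @classmethod
    def from_label(cls, label: str) -> "JointGenotype":
        try:
            prot, re = label.split(":")
        except ValueError as exc:
            raise UnknownGenotypeError(f"bad joint label {label!r}") from exc
        return cls(ProteinGenotype.from_label(prot), REGenotype.from_label(re))

    @classmethod
    def from_labels(cls, protein: str, re: str) -> "JointGenotype":
        return cls(ProteinGenotype.from_label(protein), REGenotype.from_label(re))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


ANCSR1 = ProteinGenotype(False, False, False)
ERE = REGenotype("G", "T")
SRE1 = REGenotype("A", "A")
SRE2 = REGenotype("G", "A")


def enumerate_protein_genotypes() -> list[ProteinGenotype]:
    """All 8 RH variants, all-ancestral first, then by Hamming distance,
    ties broken with site 25 varying slowest."""
    gts = [ProteinGenotype(*flags) for flags in itertools.product((False, True), repeat=3)]
    gts.sort(key=lambda g: (g.hamming, tuple(not f for f in g.states)))
    return gts


def enumerate_re_genotypes() -> list[REGenotype]:
    """All 16 half-site variants in lexicographic (A<C<G<T) order."""
    return [REGenotype(a, b) for a, b in itertools.product(NUCLEOTIDES, repeat=2)]


def enumerate_joint_genotypes() -> list[JointGenotype]:
    """All 128 complexes, protein-major order."""
    return [
        JointGenotype(p, r)
        for p in enumerate_protein_genotypes()
        for r in enumerate_re_genotypes()
    ]


def wyk_encode(nucleotide: str) -> np.ndarray:
    """Tetrahedral (w, y, k) three-vector for one nucleotide."""
    try:
        return np.array(WYK[nucleotide], dtype=float)
    except KeyError:
        raise UnknownGenotypeError(f"invalid nucleotide {nucleotide!r}") from None


def abc_encode(state) -> int:
    """±1 coordinate for one protein site: ancestral −1, derived +1.

    Accepts a bool derived-flag or the strings ``"ancestral"``/``"derived"``.
    """
    if isinstance(state, str):
        if state not in ("ancestral", "derived"):
            raise UnknownGenotypeError(f"invalid protein state {state!r}")
        state = state == "derived"
    return 1 if state else -1


# ---------------------------------------------------------------------------
# Term groups
# ---------------------------------------------------------------------------

_BASE_COORDS = ("a", "b", "c", "w3", "y3", "k3", "w4", "y4", "k4")
_SITE_OF = {"a": 25, "b": 26, "c": 29}
_RE_COORDS = {3: ("w3", "y3", "k3"), 4: ("w4", "y4", "k4")}
_PROT_PAIRS = (("a", "b"), ("a", "c"), ("b", "c"))

def _re_pair_terms() -> list[tuple[str, ...]]:
    return [(x, y) for x in _RE_COORDS[3] for y in _RE_COORDS[4]]


def _build_term_factors() -> dict[str, dict[str, tuple[str, ...]]]:
    """Ordered {group: {term name: base-coordinate factors}} for abc_wyk."""
    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    groups["INTERCEPT"] = {"u0": ()}
    groups["P1"] = {v: (v,) for v in ("a", "b", "c")}
    groups["P2"] = {i + j: (i, j) for i, j in _PROT_PAIRS}
    groups["R1_3"] = {v: (v,) for v in _RE_COORDS[3]}
    groups["R1_4"] = {v: (v,) for v in _RE_COORDS[4]}
    groups["R2"] = {x[0] + x[1]: x for x in _re_pair_terms()}
    groups["X2"] = {
        f"{p}:{r}": (p, r)
        for p in ("a", "b", "c")
        for r in _RE_COORDS[3] + _RE_COORDS[4]
    }
    x3: dict[str, tuple[str, ...]] = {}
    for p in ("a", "b", "c"):
        for x, y in _re_pair_terms():
            x3[f"{p}:{x}{y}"] = (p, x, y)
    for i, j in _PROT_PAIRS:
        for r in _RE_COORDS[3] + _RE_COORDS[4]:
            x3[f"{i}{j}:{r}"] = (i, j, r)
    groups["X3"] = x3
    groups["P3"] = {"abc": ("a", "b", "c")}
    return groups


TERM_GROUPS = _build_term_factors()
CANONICAL_GROUP_ORDER = tuple(TERM_GROUPS)  # INTERCEPT..X3, P3 optional last
GROUP_SIZES = {g: len(t) for g, t in TERM_GROUPS.items()}


@dataclass(frozen=True)
class ModelSpec:
    """An ordered selection of term groups defining one regression model.

    Groups are always arranged in the canonical nesting order
    INTERCEPT, P1, P2, R1_3, R1_4, R2, X2, X3, P3; the intercept is
    mandatory.
    """

    groups: tuple[str, ...] = ("INTERCEPT",)

    def __post_init__(self) -> None:
        unknown = [g for g in self.groups if g not in TERM_GROUPS]
        if unknown:
            raise ValueError(f"unknown term groups: {unknown}")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate term groups")
        ordered = tuple(g for g in CANONICAL_GROUP_ORDER if g in self.groups)
        if "INTERCEPT" not in ordered:
            ordered = ("INTERCEPT",) + ordered
        object.__setattr__(self, "groups", ordered)

    @classmethod
    def from_names(cls, *names: str) -> "ModelSpec":
        return cls(tuple(names))

    @property
    def terms(self) -> list[str]:
        return [t for g in self.groups for t in TERM_GROUPS[g]]

    @property
    def n_columns(self) -> int:
        return sum(GROUP_SIZES[g] for g in self.groups)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.groups) <= set(other.groups)

    def with_groups(self, *extra: str) -> "ModelSpec":
        return ModelSpec(self.groups + tuple(g for g in extra if g not in self.groups))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return "+".join(self.groups)


#: The model hierarchy used throughout: everything through third order.
FULL_SPEC = ModelSpec(("INTERCEPT", "P1", "P2", "R1_3", "R1_4", "R2", "X2", "X3"))
#: Saturated per-protein RE model: 16 parameters for 16 half-site cells.
RE_SPEC = ModelSpec(("INTERCEPT", "R1_3", "R1_4", "R2"))


def base_coordinates(genotype: JointGenotype) -> dict[str, float]:
    """The nine elementary ±1 coordinates of one joint genotype."""
    coords = dict(
        zip(("a", "b", "c"), (abc_encode(f) for f in genotype.protein.states))
    )
    for site, nuc in ((3, genotype.re.n3), (4, genotype.re.n4)):
        coords.update(zip(_RE_COORDS[site], wyk_encode(nuc)))
    return coords


def encode_genotype(genotype: JointGenotype, spec: ModelSpec) -> np.ndarray:
    """abc/WYK encoding vector (products included) for one genotype."""
    coords = base_coordinates(genotype)
    out = np.empty(spec.n_columns)
    i = 0
    for g in spec.groups:
        for factors in TERM_GROUPS[g].values():
            v = 1.0
            for f in factors:
                v *= coords[f]
            out[i] = v
            i += 1
    return out


# ---------------------------------------------------------------------------
# Binary (indicator) encoding
# ---------------------------------------------------------------------------

def _protein_state_atoms() -> list[tuple[str, tuple]]:
    atoms = []
    for site in PROTEIN_SITES:
        for res in RESIDUES[site]:
            atoms.append((f"{res}{site}", ("protein", site, res)))
    return atoms


def _re_state_atoms(site: int) -> list[tuple[str, tuple]]:
    return [(f"{n}{site}", ("re", site, n)) for n in NUCLEOTIDES]


def _binary_groups() -> dict[str, dict[str, tuple[tuple, ...]]]:
    prot = _protein_state_atoms()
    prot_by_site = {
        site: [a for a in prot if a[1][1] == site] for site in PROTEIN_SITES
    }
    re3, re4 = _re_state_atoms(3), _re_state_atoms(4)
    groups: dict[str, dict[str, tuple[tuple, ...]]] = {}
    groups["INTERCEPT"] = {"u0": ()}
    groups["P1"] = {name: (cond,) for name, cond in prot}
    groups["P2"] = {}
    for (si, sj) in itertools.combinations(PROTEIN_SITES, 2):
        for (ni, ci), (nj, cj) in itertools.product(
            prot_by_site[si], prot_by_site[sj]
        ):
            groups["P2"][f"{ni}_{nj}"] = (ci, cj)
    groups["R1_3"] = {name: (cond,) for name, cond in re3}
    groups["R1_4"] = {name: (cond,) for name, cond in re4}
    groups["R2"] = {
        f"{n3}_{n4}": (c3, c4) for (n3, c3), (n4, c4) in itertools.product(re3, re4)
    }
    groups["X2"] = {}
    for np_, cp in prot:
        for nr, cr in re3 + re4:
            groups["X2"][f"{np_}_{nr}"] = (cp, cr)
    x3: dict[str, tuple[tuple, ...]] = {}
    for np_, cp in prot:
        for (n3, c3), (n4, c4) in itertools.product(re3, re4):
            x3[f"{np_}_{n3}_{n4}"] = (cp, c3, c4)
    for pair_name, conds in groups["P2"].items():
        for nr, cr in re3 + re4:
            x3[f"{pair_name}_{nr}"] = conds + (cr,)
    groups["X3"] = x3
    groups["P3"] = {}
    for (na, ca), (nb, cb), (nc, cc) in itertools.product(
        prot_by_site[25], prot_by_site[26], prot_by_site[29]
    ):
        groups["P3"][f"{na}_{nb}_{nc}"] = (ca, cb, cc)
    return groups


BINARY_GROUPS = _binary_groups()


def _condition_holds(genotype: JointGenotype, cond: tuple) -> bool:
    kind, site, state = cond
    if kind == "protein":
        return genotype.protein.residue(site) == state
    return (genotype.re.n3 if site == 3 else genotype.re.n4) == state


def binary_encode(genotype: JointGenotype, spec: ModelSpec) -> np.ndarray:
    """Indicator encoding: each column 1 iff all its genetic states are present."""
    out = np.empty(sum(len(BINARY_GROUPS[g]) for g in spec.groups))
    i = 0
    for g in spec.groups:
        for conds in BINARY_GROUPS[g].values():
            out[i] = float(all(_condition_holds(genotype, c) for c in conds))
            i += 1
    return out


def binary_terms(spec: ModelSpec) -> list[str]:
    return [t for g in spec.groups for t in BINARY_GROUPS[g]]


Encoding = Literal["abc_wyk", "binary"]


def build_design_matrix(
    observations: Iterable[JointGenotype | str],
    spec: ModelSpec,
    encoding: Encoding = "abc_wyk",
) -> pd.DataFrame:
    """Design matrix with one row per observation, term-labelled columns.

    ``observations`` may be ``JointGenotype`` objects or their string labels
    (``"glu-gly-ala:GT"``).
    """
    gts = [
        g if isinstance(g, JointGenotype) else JointGenotype.from_label(g)
        for g in observations
    ]
    if not gts:
        raise ValueError("empty observation set")
    if encoding == "abc_wyk":
        rows = np.array([encode_genotype(g, spec) for g in gts])
        cols = spec.terms
    elif encoding == "binary":
        rows = np.array([binary_encode(g, spec) for g in gts])
        cols = binary_terms(spec)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return pd.DataFrame(rows, columns=cols, index=[g.label for g in gts])


# ---------------------------------------------------------------------------
# Moves and neighbourhoods
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Move:
    """Set one position of one molecule to a given state.

    ``molecule`` is ``"protein"`` or ``"re"``; ``site`` the position number;
    ``to_state`` the residue or nucleotide installed.
    """

    molecule: str
    site: int
    to_state: str

    @property
    def label(self) -> str:
        return f"{self.molecule}:{self.site}->{self.to_state}"


def is_applicable(move: Move, genotype: JointGenotype) -> bool:
    if move.molecule == "protein":
        return genotype.protein.residue(move.site) != move.to_state
    cur = genotype.re.n3 if move.site == 3 else genotype.re.n4
    return cur != move.to_state


def apply_move(move: Move, genotype: JointGenotype) -> JointGenotype:
    if not is_applicable(move, genotype):
        raise ValueError(f"move {move.label} is a no-op on {genotype.label}")
    if move.molecule == "protein":
        idx = PROTEIN_SITES.index(move.site)
        flags = list(genotype.protein.states)
        flags[idx] = move.to_state == RESIDUES[move.site][1]
        return JointGenotype(ProteinGenotype(*flags), genotype.re)
    if move.site == 3:
        return JointGenotype(genotype.protein, REGenotype(move.to_state, genotype.re.n4))
    return JointGenotype(genotype.protein, REGenotype(genotype.re.n3, move.to_state))


def available_moves(genotype: JointGenotype) -> list[Move]:
    """The 9 single-change moves from a joint genotype: 3 protein
    replacements plus 2 sites x 3 alternative nucleotides."""
    moves = []
    for site, flag in zip(PROTEIN_SITES, genotype.protein.states):
        moves.append(Move("protein", site, RESIDUES[site][not flag]))
    for site, cur in ((3, genotype.re.n3), (4, genotype.re.n4)):
        for n in NUCLEOTIDES:
            if n != cur:
                moves.append(Move("re", site, n))
    return moves


def neighbors(genotype: JointGenotype) -> list[tuple[JointGenotype, Move]]:
    """The 9 single-change neighbours, each tagged with its move."""
    return [(apply_move(m, genotype), m) for m in available_moves(genotype)]


def probe_sequence(re: REGenotype) -> str:
    """Forward-strand 8-mer probe for one half-site variant (CCAG--CA)."""
    return _PROBE_PREFIX + re.n3 + re.n4 + _PROBE_SUFFIX
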