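"""Synthetic landscapes, measurement tables, titrations and fixtures.

The generator is the inverse of the regression hierarchy: landscape
parameters are specified in interpretable *effect space* (state effects
as zero-sum deviations from the grand mean; pair contrasts with zero
row/column sums; protein substitution effects and pair marginals on the
paper-style 2x-coefficient scale; cross-interface shifts as the change a
substitution causes in a nucleotide effect or pair contrast) and
converted internally to the per-cell contributions the encoded models
recover.  Replicate observations add independent Gaussian noise.

Every printed-in-text effect used in a preset is tagged
``provenance="paper"``; every magnitude the source shows only
graphically is a documented placeholder tagged ``provenance="placeholder"``
so that no invented number can masquerade as a measured one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import DEFAULT_PROBE_CONC_M, TitrationCurve
from .genotype_space import (
    ANCSR1,
    ERE,
    NUCLEOTIDES,
    PROTEIN_SITES,
    JointGenotype,
    ProteinGenotype,
    REGenotype,
    abc_encode,
    enumerate_joint_genotypes,
    enumerate_protein_genotypes,
)

__all__ = [
    "LandscapeParams",
    "Fixture",
    "generate_landscape",
    "generate_titration",
    "preset_ancsr1",
    "pathway_fixtures",
    "random_landscape_params",
    "pair_contrast_matrix",
]

_PROT_PAIRS = ((25, 26), (25, 29), (26, 29))
_ZERO_TOL = 1e-9


def pair_contrast_matrix(
    row_state: str, entries: dict[str, float]
) -> dict[tuple[str, str], float]:
    """Smallest doubly-centred 4x4 contrast matrix with given entries.

    The specified entries all sit in the site-3 row ``row_state``;
    unspecified entries of that row absorb the balance evenly and the
    other three rows each take −1/3 of every column value, which keeps
    all row and column sums at zero.
    """
    free = [n for n in NUCLEOTIDES if n not in entries]
    spill = -sum(entries.values()) / len(free) if free else 0.0
    if not free and abs(sum(entries.values())) > _ZERO_TOL:
        raise ValueError("fully specified row must sum to zero")
    row = {n: entries.get(n, spill) for n in NUCLEOTIDES}
    mat = {}
    for n3 in NUCLEOTIDES:
        for n4 in NUCLEOTIDES:
            mat[(n3, n4)] = row[n4] if n3 == row_state else -row[n4] / 3.0
    return mat


def _check_zero_sum(values, what: str) -> None:
    if abs(sum(values)) > _ZERO_TOL:
        raise ValueError(f"{what} must sum to zero (got {sum(values):g})")


def _check_pair_matrix(mat: dict[tuple[str, str], float], what: str) -> None:
    for n3 in NUCLEOTIDES:
        _check_zero_sum((mat.get((n3, n4), 0.0) for n4 in NUCLEOTIDES), f"{what} row {n3}")
    for n4 in NUCLEOTIDES:
        _check_zero_sum((mat.get((n3, n4), 0.0) for n3 in NUCLEOTIDES), f"{what} column {n4}")


@dataclass
class LandscapeParams:
    """Generative parameters of one 8 x 16 binding-energy landscape.

    All effect magnitudes are kcal/mol.  ``re_site_effects`` are per-site
    state deviations (zero-sum over the four nucleotides);
    ``re_pair_contrasts`` a doubly-centred 4x4 matrix keyed (n3, n4);
    ``protein_effects`` total substitution effects (derived minus
    ancestral background mean); ``protein_pair_marginals`` marginal
    interactions on the same 2x-coefficient scale; ``cross_state_shifts``
    keyed (protein site, RE site) give the change each substitution
    causes in each nucleotide state effect (zero-sum over states);
    ``third_order_pair_shifts`` (per protein site) the change in each RE
    pair contrast; ``third_order_state_shifts`` keyed (protein pair, RE
    site) the change a pair of substitutions causes in each state effect.
    """

    grand_mean: float = 10.0
    re_site_effects: dict[int, dict[str, float]] = field(default_factory=dict)
    re_pair_contrasts: dict[tuple[str, str], float] = field(default_factory=dict)
    protein_effects: dict[int, float] = field(default_factory=dict)
    protein_pair_marginals: dict[tuple[int, int], float] = field(default_factory=dict)
    cross_state_shifts: dict[tuple[int, int], dict[str, float]] = field(default_factory=dict)
    third_order_pair_shifts: dict[int, dict[tuple[str, str], float]] = field(default_factory=dict)
    third_order_state_shifts: dict[tuple[tuple[int, int], int], dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.2
    replicates: int = 3
    seed: int = 0
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("at least one replicate per cell")
        for site, effects in self.re_site_effects.items():
            _check_zero_sum(effects.values(), f"site-{site} state effects")
        if self.re_pair_contrasts:
            _check_pair_matrix(self.re_pair_contrasts, "RE pair contrasts")
        for key, shifts in self.cross_state_shifts.items():
            _check_zero_sum(shifts.values(), f"cross shifts {key}")
        for site, mat in self.third_order_pair_shifts.items():
            _check_pair_matrix(mat, f"third-order pair shifts (site {site})")
        for key, shifts in self.third_order_state_shifts.items():
            _check_zero_sum(shifts.values(), f"third-order state shifts {key}")

    # -- generative model --------------------------------------------------

    def cell_mean(self, genotype: JointGenotype) -> float:
        """Expected ΔG_dissociation of one complex under these parameters."""
        n3, n4 = genotype.re.n3, genotype.re.n4
        u = {
            site: abc_encode(flag)
            for site, flag in zip(PROTEIN_SITES, genotype.protein.states)
        }
        v = self.grand_mean
        v += self.re_site_effects.get(3, {}).get(n3, 0.0)
        v += self.re_site_effects.get(4, {}).get(n4, 0.0)
        v += self.re_pair_contrasts.get((n3, n4), 0.0)
        for site, eff in self.protein_effects.items():
            v += u[site] * eff / 2.0
        for (i, j), marg in self.protein_pair_marginals.items():
            v += u[i] * u[j] * marg / 2.0
        for (p, rsite), shifts in self.cross_state_shifts.items():
            state = n3 if rsite == 3 else n4
            v += u[p] * shifts.get(state, 0.0) / 2.0
        for p, mat in self.third_order_pair_shifts.items():
            v += u[p] * mat.get((n3, n4), 0.0) / 2.0
        for ((i, j), rsite), shifts in self.third_order_state_shifts.items():
            state = n3 if rsite == 3 else n4
            v += u[i] * u[j] * shifts.get(state, 0.0) / 2.0
        return v


def generate_landscape(
    params: LandscapeParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-level measurement table and cell-mean landscape.

    Deterministic for a given seed: replicate noise is drawn from
    ``numpy.random.default_rng(params.seed)`` in canonical genotype order.
    """
    rng = np.random.default_rng(params.seed)
    genotypes = enumerate_joint_genotypes()
    means = {g: params.cell_mean(g) for g in genotypes}
    r = params.replicates
    mean_arr = np.repeat([means[g] for g in genotypes], r)
    noise = (
        rng.normal(0.0, params.noise_sd, size=mean_arr.size)
        if params.noise_sd > 0
        else 0.0
    )
    table = pd.DataFrame(
        {
            "protein": np.repeat([g.protein.label for g in genotypes], r),
            "re": np.repeat([g.re.label for g in genotypes], r),
            "replicate": np.tile(np.arange(1, r + 1), len(genotypes)),
            "dG_kcal_mol": mean_arr + noise,
        }
    )
    landscape = pd.DataFrame(
        {
            "protein": [g.protein.label for g in genotypes],
            "re": [g.re.label for g in genotypes],
            "mean_dG": [means[g] for g in genotypes],
        }
    )
    return table, landscape


def generate_titration(
    Kd_M: float,
    baseline: float = 0.05,
    plateau: float = 0.25,
    concentrations_M=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    protein: ProteinGenotype = ANCSR1,
    probe: REGenotype = ERE,
    replicate: int = 1,
    probe_conc_M: float = DEFAULT_PROBE_CONC_M,
) -> TitrationCurve:
    """Single-site hyperbolic titration with Gaussian anisotropy noise.

    Default concentrations span 1.5 log decades either side of K_d at 12
    points, mirroring a typical anisotropy titration layout.
    """
    if Kd_M <= 0:
        raise ValueError("K_d must be positive")
    if concentrations_M is None:
        concentrations_M = np.geomspace(Kd_M / 10 ** 1.5, Kd_M * 10 ** 1.5, 12)
    conc = np.asarray(concentrations_M, dtype=float)
    if conc.size < 5:
        raise ValueError("at least 5 concentrations required")
    rng = np.random.default_rng(seed)
    a = baseline + (plateau - baseline) * conc / (Kd_M + conc)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=conc.size)
    return TitrationCurve(
        protein=protein,
        probe=probe,
        replicate=replicate,
        concentrations_M=tuple(conc),
        anisotropy=tuple(a),
        probe_conc_M=probe_conc_M,
    )


# ---------------------------------------------------------------------------
# Presets and fixtures
# ---------------------------------------------------------------------------

def preset_ancsr1(
    noise_sd: float = 0.2, replicates: int = 3, seed: int = 0
) -> LandscapeParams:
    """AncSR1-style landscape parameters.

    Effects printed in the source's Results text (G3 +1.0, T4 +0.5,
    G3xT4 +0.8, glu25GLY +1.3 kcal/mol) are tagged ``paper``; every other
    determinant — shown there only as logo graphics — is a documented
    placeholder of realistic magnitude tagged ``placeholder``.
    """
    site3 = {"G": 1.0, "A": -1.0 / 3, "C": -1.0 / 3, "T": -1.0 / 3}
    site4 = {"T": 0.5, "A": -0.5 / 3, "C": -0.5 / 3, "G": -0.5 / 3}
    pair = pair_contrast_matrix("G", {"T": 0.8, "A": -0.6})
    params = LandscapeParams(
        grand_mean=10.0,
        re_site_effects={3: site3, 4: site4},
        re_pair_contrasts=pair,
        protein_effects={25: 1.3, 26: -0.5, 29: -0.4},
        protein_pair_marginals={(25, 26): -0.2, (25, 29): 0.15, (26, 29): -0.1},
        cross_state_shifts={
            (25, 3): {"G": -0.4, "A": 0.4, "C": 0.0, "T": 0.0},
            (25, 4): {"T": -0.3, "A": 0.3, "C": 0.0, "G": 0.0},
            (26, 3): {"G": -0.2, "A": 0.2, "C": 0.0, "T": 0.0},
            (29, 4): {"T": -0.2, "A": 0.2, "C": 0.0, "G": 0.0},
        },
        third_order_pair_shifts={
            26: pair_contrast_matrix("G", {"T": -0.2, "A": 0.2}),
            29: pair_contrast_matrix("G", {"T": -0.15, "A": 0.15}),
        },
        noise_sd=noise_sd,
        replicates=replicates,
        seed=seed,
        provenance={
            "re_site_effects.3.G": "paper",
            "re_site_effects.3.other": "placeholder",
            "re_site_effects.4.T": "paper",
            "re_site_effects.4.other": "placeholder",
            "re_pair_contrasts.G3T4": "paper",
            "re_pair_contrasts.G3A4": "placeholder",
            "re_pair_contrasts.other": "placeholder",
            "protein_effects.25": "paper",
            "protein_effects.26": "placeholder",
            "protein_effects.29": "placeholder",
            "protein_pair_marginals": "placeholder",
            "cross_state_shifts": "placeholder",
            "third_order_pair_shifts": "placeholder",
            "grand_mean": "placeholder",
        },
    )
    return params


def random_landscape_params(
    seed: int,
    noise_sd: float = 0.0,
    replicates: int = 1,
    scale: float = 0.5,
    with_cross: bool = True,
) -> LandscapeParams:
    """A random valid parameter set (zero-sum constraints enforced by
    centring), for property tests of the generator/model round trip."""
    rng = np.random.default_rng(seed)

    def centred(n):
        v = rng.normal(0.0, scale, n)
        return v - v.mean()

    def centred_matrix():
        m = rng.normal(0.0, scale, (4, 4))
        m = m - m.mean(axis=1, keepdims=True)
        m = m - m.mean(axis=0, keepdims=True)
        return {
            (n3, n4): float(m[i, j])
            for i, n3 in enumerate(NUCLEOTIDES)
            for j, n4 in enumerate(NUCLEOTIDES)
        }

    params = LandscapeParams(
        grand_mean=float(rng.normal(10.0, 1.0)),
        re_site_effects={
            3: dict(zip(NUCLEOTIDES, centred(4))),
            4: dict(zip(NUCLEOTIDES, centred(4))),
        },
        re_pair_contrasts=centred_matrix(),
        protein_effects={s: float(rng.normal(0.0, scale)) for s in PROTEIN_SITES},
        protein_pair_marginals={
            p: float(rng.normal(0.0, scale)) for p in _PROT_PAIRS
        },
        cross_state_shifts=(
            {
                (p, r): dict(zip(NUCLEOTIDES, centred(4)))
                for p in PROTEIN_SITES
                for r in (3, 4)
            }
            if with_cross
            else {}
        ),
        third_order_pair_shifts=(
            {p: centred_matrix() for p in PROTEIN_SITES} if with_cross else {}
        ),
        third_order_state_shifts=(
            {
                (pair, r): dict(zip(NUCLEOTIDES, centred(4)))
                for pair in _PROT_PAIRS
                for r in (3, 4)
            }
            if with_cross
            else {}
        ),
        noise_sd=noise_sd,
        replicates=replicates,
        seed=seed,
    )
    return params


@dataclass
class Fixture:
    """A named landscape with the qualitative outcomes tests expect."""

    name: str
    landscape: dict[JointGenotype, float]
    expected: dict
    functional_set: set[JointGenotype] | None = None


def _uniform_landscape(value: float) -> dict[JointGenotype, float]:
    return {g: value for g in enumerate_joint_genotypes()}


def pathway_fixtures() -> dict[str, Fixture]:
    """Hand-built landscapes exercising the pathway machinery.

    ``all_functional`` additionally carries an explicit all-128
    functional set for graph-level checks: the two-criterion rule itself
    can never call every complex functional (strictly above the grand
    mean fails for at least one cell), so the fully connected case is a
    constructed graph input, not a classifiable landscape.
    """
    fixtures: dict[str, Fixture] = {}

    # each protein functional on GT; all orderings accessible
    high_gt = _uniform_landscape(8.0)
    for p in enumerate_protein_genotypes():
        high_gt[JointGenotype(p, REGenotype("G", "T"))] = 12.0
    fixtures["all_functional"] = Fixture(
        name="all_functional",
        landscape=high_gt,
        expected={"accessible_orderings": 6, "edges_all_128": 576},
        functional_set=set(enumerate_joint_genotypes()),
    )

    fixtures["none_functional"] = Fixture(
        name="none_functional",
        landscape=_uniform_landscape(9.0),
        expected={"accessible_orderings": 0, "functional": 0},
    )

    # only proteins carrying the site-25 replacement (or the ancestor) work
    gateway = _uniform_landscape(8.0)
    gateway[JointGenotype(ANCSR1, REGenotype("G", "T"))] = 12.0
    for p in enumerate_protein_genotypes():
        if p.derived25:
            gateway[JointGenotype(p, REGenotype("G", "T"))] = 12.0
    fixtures["single_gateway"] = Fixture(
        name="single_gateway",
        landscape=gateway,
        expected={"accessible_orderings": 2, "first_move": "glu25GLY"},
    )

    # functional set = all proteins x {GT}: a Cartesian product, no gating
    fixtures["separable"] = Fixture(
        name="separable",
        landscape=dict(high_gt),
        expected={"gating_events": 0},
    )

    # GT->TT blocked for the ancestor, open after glu25GLY
    perm = _uniform_landscape(8.0)
    d25 = ProteinGenotype(True, False, False)
    perm[JointGenotype(ANCSR1, REGenotype("G", "T"))] = 12.0
    perm[JointGenotype(d25, REGenotype("G", "T"))] = 12.0
    perm[JointGenotype(d25, REGenotype("T", "T"))] = 12.0
    fixtures["permissive_4node"] = Fixture(
        name="permissive_4node",
        landscape=perm,
        expected={
            "permissive_context": "glu-gly-ala:GT",
            "gating_move": "protein:25->GLY",
            "focal_move": "re:3->T",
        },
    )
    return fixtures
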