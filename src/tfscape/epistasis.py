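"""Nested linear models of binding energy over the joint sequence space.

Binding free energy ΔG_dissociation is regressed on encoded genotype
coordinates.  Under the abc/WYK encoding every column is a mean-centred
±1 contrast, so on the complete balanced 8 x 16 factorial the intercept
u0 equals the grand mean, each coefficient is orthogonal to every other,
and genetic effects read directly off the coefficients:

* state effect of nucleotide s at RE site i:  (w_i, y_i, k_i) · WYK(s)
* pairwise RE epistasis of (s3, s4):  Σ coef[xy] · WYK(s3)⊗WYK(s4)
* total effect of a protein substitution:  2 x its coefficient
* marginal protein-pair interaction:  2 x the pair coefficient
* cross-interface shift of a nucleotide effect caused by a substitution:
  2 x (that substitution's cross coefficients · the state's WYK vector)

Model comparison uses Gaussian likelihood-ratio tests (variance profiled
at the MLE, asymptotic chi-square reference with df = added columns) and
adjusted-R² increments, Bonferroni-corrected within a declared family.

Fits under the redundant ``binary`` indicator encoding use minimum-norm
least squares; effects are then extracted from fitted cell means via the
definitional contrasts, which lets the two encodings cross-validate one
another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .genotype_space import (
    PROTEIN_SITES,
    WYK,
    JointGenotype,
    ModelSpec,
    RE_SPEC,
    TERM_GROUPS,
    _RE_COORDS,
    build_design_matrix,
    wyk_encode,
)

__all__ = [
    "EpistasisRegression",
    "NestedComparison",
    "EnergyLogo",
    "RankDeficiencyError",
    "fit_model",
    "compare_nested",
    "state_effect",
    "pair_epistasis",
    "substitution_effect",
    "protein_pair_epistasis",
    "cross_interface_effect",
    "cross_interface_pair_effect",
    "variance_partition",
    "build_energy_logo",
    "energy_logo_for_protein",
    "logo_comparisons",
]

logger = logging.getLogger(__name__)

_SITE_COEF = {25: "a", 26: "b", 29: "c"}
_PAIR_COEF = {(25, 26): "ab", (25, 29): "ac", (26, 29): "bc"}


class RankDeficiencyError(ValueError):
    """The abc/WYK design matrix is column-rank deficient."""


def _as_measurement_frame(table: pd.DataFrame) -> pd.DataFrame:
    required = {"protein", "re", "dG_kcal_mol"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return table


class EpistasisRegression(BaseEstimator):
    """OLS fit of an encoded term-group model to binding measurements.

    Parameters
    ----------
    spec : ModelSpec
        Ordered term-group selection (intercept always included).
    encoding : {"abc_wyk", "binary"}
        Contrast encoding of the genotype coordinates.

    Fitted attributes: ``coef_`` (Series keyed by term name), ``llf_``,
    ``r2_``, ``adj_r2_``, ``resid_sd_``, ``n_obs_``, ``rank_``,
    ``fitted_``, ``genotypes_``.
    """

    def __init__(self, spec: ModelSpec = RE_SPEC, encoding: str = "abc_wyk"):
        self.spec = spec
        self.encoding = encoding

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit to a measurement table or to (genotypes, ΔG values).

        ``X`` may be a DataFrame with columns ``protein``, ``re``,
        ``dG_kcal_mol`` (and optionally ``censored``), or a sequence of
        joint genotypes / labels with ``y`` the energies.
        """
        if isinstance(X, pd.DataFrame) and y is None:
            tab = _as_measurement_frame(X)
            if "censored" in tab.columns:
                n_censored = int(tab["censored"].sum())
                if n_censored:
                    logger.info("excluding %d censored rows", n_censored)
                tab = tab[~tab["censored"].astype(bool)]
            genotypes = [
                JointGenotype.from_labels(p, r)
                for p, r in zip(tab["protein"], tab["re"])
            ]
            yv = tab["dG_kcal_mol"].to_numpy(dtype=float)
        else:
            genotypes = [
                g if isinstance(g, JointGenotype) else JointGenotype.from_label(g)
                for g in X
            ]
            yv = np.asarray(y, dtype=float).ravel()
        if len(genotypes) != yv.size:
            raise ValueError("genotype/response length mismatch")
        if not np.all(np.isfinite(yv)):
            raise ValueError("non-finite ΔG among uncensored rows")

        design = build_design_matrix(genotypes, self.spec, self.encoding)
        Xm = design.to_numpy()
        n, p = Xm.shape
        if self.encoding == "abc_wyk":
            rank = np.linalg.matrix_rank(Xm)
            if rank < p:
                _, _, piv = linalg.qr(Xm, mode="economic", pivoting=True)
                collinear = [design.columns[i] for i in sorted(piv[rank:])]
                raise RankDeficiencyError(
                    f"design matrix rank {rank} < {p} columns; "
                    f"collinear terms: {collinear}"
                )
            res = sm.OLS(yv, Xm).fit()
            beta = np.asarray(res.params)
            fitted = np.asarray(res.fittedvalues)
        else:
            # redundant one-hot design: minimum-norm least squares
            beta, _, rank, _ = np.linalg.lstsq(Xm, yv, rcond=None)
            fitted = Xm @ beta
        if self.encoding == "abc_wyk":
            rank = p
        rss = float(np.sum((yv - fitted) ** 2))
        tss = float(np.sum((yv - yv.mean()) ** 2))
        if tss > 0:
            r2 = 1.0 - rss / tss
        else:
            r2 = 1.0 if rss <= 1e-12 else 0.0
        dfr = n - rank
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dfr if dfr > 0 else float("nan")

        self.design_ = design
        self.genotypes_ = genotypes
        self.y_ = yv
        self.coef_ = pd.Series(beta, index=design.columns)
        self.fitted_ = np.asarray(fitted)
        self.rank_ = int(rank)
        self.n_obs_ = n
        self.rss_ = rss
        self.resid_sd_ = math.sqrt(rss / dfr) if dfr > 0 else 0.0
        self.llf_ = _gaussian_llf(n, rss)
        self.r2_ = r2
        self.adj_r2_ = adj_r2
        return self

    def predict(self, X):
        design = build_design_matrix(
            [g if isinstance(g, JointGenotype) else JointGenotype.from_label(g) for g in X],
            self.spec,
            self.encoding,
        )
        return design.to_numpy() @ self.coef_.to_numpy()

    # -- effect extraction -------------------------------------------------

    def _require_groups(self, *groups: str) -> None:
        missing = [g for g in groups if g not in self.spec.groups]
        if missing:
            raise ValueError(f"model was fitted without term groups {missing}")

    def state_effect(self, re_site: int, nucleotide: str) -> float:
        """Main effect (kcal/mol) of one nucleotide at RE site 3 or 4,
        as a deviation from the grand mean."""
        self._require_groups("R1_3" if re_site == 3 else "R1_4")
        if self.encoding == "abc_wyk":
            coefs = self.coef_[list(_RE_COORDS[re_site])].to_numpy()
            return float(coefs @ wyk_encode(nucleotide))
        f = self.fitted_
        has = np.array(
            [
                (g.re.n3 if re_site == 3 else g.re.n4) == nucleotide
                for g in self.genotypes_
            ]
        )
        return float(f[has].mean() - f.mean())

    def pair_epistasis(self, state3: str, state4: str) -> float:
        """Epistatic contrast (kcal/mol) of a nucleotide combination at
        RE sites 3 x 4: the excess over additivity of the two main effects."""
        self._require_groups("R2")
        if self.encoding == "abc_wyk":
            outer = np.outer(wyk_encode(state3), wyk_encode(state4)).ravel()
            names = [x + y for x in _RE_COORDS[3] for y in _RE_COORDS[4]]
            return float(self.coef_[names].to_numpy() @ outer)
        f = self.fitted_
        m3 = np.array([g.re.n3 == state3 for g in self.genotypes_])
        m4 = np.array([g.re.n4 == state4 for g in self.genotypes_])
        return float(
            f[m3 & m4].mean()
            - f.mean()
            - self.state_effect(3, state3)
            - self.state_effect(4, state4)
        )

    def substitution_effect(self, protein_site: int) -> float:
        """Total average effect (kcal/mol) of one RH substitution:
        derived-background mean minus ancestral-background mean (= 2 x coef)."""
        self._require_groups("P1")
        if self.encoding == "abc_wyk":
            return 2.0 * float(self.coef_[_SITE_COEF[protein_site]])
        f = self.fitted_
        der = self._protein_mask(protein_site, derived=True)
        return float(f[der].mean() - f[~der].mean())

    def protein_pair_epistasis(
        self, site_i: int, site_j: int, convention: str = "marginal"
    ) -> float:
        """Interaction between two RH substitutions.

        ``marginal`` (default): the substitution's effect in the derived
        background of the partner minus its background-averaged effect
        (= 2 x pair coefficient).  ``double_mutant_cycle``: the classic
        cycle deviation (= 4 x pair coefficient).
        """
        self._require_groups("P2")
        key = _PAIR_COEF[tuple(sorted((site_i, site_j)))]
        scale = {"marginal": 2.0, "double_mutant_cycle": 4.0}[convention]
        if self.encoding == "abc_wyk":
            return scale * float(self.coef_[key])
        f = self.fitted_
        di = self._protein_mask(site_i, derived=True)
        dj = self._protein_mask(site_j, derived=True)
        cond = f[di & dj].mean() - f[~di & dj].mean()  # effect of i | j derived
        avg = f[di].mean() - f[~di].mean()  # average effect of i
        marginal = float(cond - avg)
        return marginal if convention == "marginal" else 2.0 * marginal

    def cross_interface_effect(
        self, protein_site: int, re_site: int, nucleotide: str
    ) -> float:
        """Change (kcal/mol) that one RH substitution causes in the main
        effect of one nucleotide state — second-order intermolecular
        epistasis (= 2 x the cross coefficients · the state's WYK vector)."""
        self._require_groups("X2")
        if self.encoding == "abc_wyk":
            pc = _SITE_COEF[protein_site]
            names = [f"{pc}:{r}" for r in _RE_COORDS[re_site]]
            return 2.0 * float(self.coef_[names].to_numpy() @ wyk_encode(nucleotide))
        return self._split_state_contrast(protein_site, re_site, nucleotide)

    def cross_interface_pair_effect(
        self, protein_site: int, state3: str, state4: str
    ) -> float:
        """Change one RH substitution causes in an RE pair-epistasis
        contrast — third-order intermolecular epistasis."""
        self._require_groups("X3")
        if self.encoding == "abc_wyk":
            pc = _SITE_COEF[protein_site]
            names = [f"{pc}:{x}{y}" for x in _RE_COORDS[3] for y in _RE_COORDS[4]]
            outer = np.outer(wyk_encode(state3), wyk_encode(state4)).ravel()
            return 2.0 * float(self.coef_[names].to_numpy() @ outer)
        f = self.fitted_
        out = []
        for derived in (True, False):
            m = self._protein_mask(protein_site, derived=derived)
            out.append(_cell_pair_contrast(f[m], [g for g, keep in zip(self.genotypes_, m) if keep], state3, state4))
        return float(out[0] - out[1])

    def protein_pair_state_effect(
        self, site_i: int, site_j: int, re_site: int, nucleotide: str
    ) -> float:
        """Change a pair of RH substitutions causes in one nucleotide
        state effect — the other face of third-order intermolecular
        epistasis (protein pair x RE coordinate terms)."""
        self._require_groups("X3")
        pc = _PAIR_COEF[tuple(sorted((site_i, site_j)))]
        names = [f"{pc}:{r}" for r in _RE_COORDS[re_site]]
        return 2.0 * float(self.coef_[names].to_numpy() @ wyk_encode(nucleotide))

    # -- uncertainty -------------------------------------------------------

    def contrast_se(self, names: list[str], weights) -> float:
        """Standard error of a linear contrast of coefficients."""
        X = self.design_.to_numpy()
        cov = self.resid_sd_ ** 2 * np.linalg.inv(X.T @ X)
        idx = [self.design_.columns.get_loc(n) for n in names]
        c = np.zeros(X.shape[1])
        c[idx] = np.asarray(weights, dtype=float)
        return float(math.sqrt(c @ cov @ c))

    def state_effect_se(self, re_site: int, nucleotide: str) -> float:
        names = list(_RE_COORDS[re_site])
        return self.contrast_se(names, wyk_encode(nucleotide))

    def _protein_mask(self, site: int, derived: bool) -> np.ndarray:
        idx = PROTEIN_SITES.index(site)
        return np.array(
            [g.protein.states[idx] == derived for g in self.genotypes_]
        )

    def _split_state_contrast(
        self, protein_site: int, re_site: int, nucleotide: str
    ) -> float:
        f = self.fitted_
        has = np.array(
            [
                (g.re.n3 if re_site == 3 else g.re.n4) == nucleotide
                for g in self.genotypes_
            ]
        )
        vals = []
        for derived in (True, False):
            m = self._protein_mask(protein_site, derived=derived)
            vals.append(f[m & has].mean() - f[m].mean())
        return float(vals[0] - vals[1])


def _cell_pair_contrast(f, genotypes, state3, state4) -> float:
    f = np.asarray(f)
    m3 = np.array([g.re.n3 == state3 for g in genotypes])
    m4 = np.array([g.re.n4 == state4 for g in genotypes])
    eff3 = f[m3].mean() - f.mean()
    eff4 = f[m4].mean() - f.mean()
    return float(f[m3 & m4].mean() - f.mean() - eff3 - eff4)


def _gaussian_llf(n: int, rss: float) -> float:
    # variance profiled at its MLE; rss clamped away from 0 so that
    # interpolating fits stay finite
    s2 = max(rss, 1e-300) / n
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


# ---------------------------------------------------------------------------
# Module-level thin wrappers
# ---------------------------------------------------------------------------

def fit_model(
    table: pd.DataFrame, spec: ModelSpec, encoding: str = "abc_wyk"
) -> EpistasisRegression:
    """Fit one encoded model to a replicate-level measurement table."""
    return EpistasisRegression(spec=spec, encoding=encoding).fit(table)


def state_effect(fit: EpistasisRegression, re_site: int, nucleotide: str) -> float:
    return fit.state_effect(re_site, nucleotide)


def pair_epistasis(fit: EpistasisRegression, state3: str, state4: str) -> float:
    return fit.pair_epistasis(state3, state4)


def substitution_effect(fit: EpistasisRegression, protein_site: int) -> float:
    return fit.substitution_effect(protein_site)


def protein_pair_epistasis(
    fit: EpistasisRegression, site_i: int, site_j: int, convention: str = "marginal"
) -> float:
    return fit.protein_pair_epistasis(site_i, site_j, convention)


def cross_interface_effect(
    fit: EpistasisRegression, protein_site: int, re_site: int, nucleotide: str
) -> float:
    return fit.cross_interface_effect(protein_site, re_site, nucleotide)


def cross_interface_pair_effect(
    fit: EpistasisRegression, protein_site: int, state3: str, state4: str
) -> float:
    return fit.cross_interface_pair_effect(protein_site, state3, state4)


# ---------------------------------------------------------------------------
# Nested model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedComparison:
    simple: str
    complex: str
    statistic: float
    df: int
    p_value: float
    p_adjusted: float
    family_size: int
    adj_r2_increment: float


def compare_nested(
    fit_simple: EpistasisRegression,
    fit_complex: EpistasisRegression,
    family_size: int = 1,
) -> NestedComparison:
    """Likelihood-ratio test of nested encoded models on the same data.

    Statistic 2·(llf_complex − llf_simple) against chi-square with df =
    number of added design columns; Bonferroni adjustment by
    ``family_size``.  The adjusted-R² increment may be negative and is
    reported as-is.
    """
    if not fit_simple.spec.is_nested_in(fit_complex.spec):
        raise ValueError(
            f"{fit_simple.spec} is not nested in {fit_complex.spec}"
        )
    if fit_simple.n_obs_ != fit_complex.n_obs_ or not np.array_equal(
        fit_simple.y_, fit_complex.y_
    ):
        raise ValueError("nested comparison requires identical observations")
    df = fit_complex.rank_ - fit_simple.rank_
    if df == 0:
        stat, p = 0.0, 1.0
    else:
        stat = max(0.0, 2.0 * (fit_complex.llf_ - fit_simple.llf_))
        p = float(chi2.sf(stat, df))
    return NestedComparison(
        simple=str(fit_simple.spec),
        complex=str(fit_complex.spec),
        statistic=stat,
        df=df,
        p_value=p,
        p_adjusted=min(1.0, p * family_size),
        family_size=family_size,
        adj_r2_increment=fit_complex.adj_r2_ - fit_simple.adj_r2_,
    )


def variance_partition(
    table: pd.DataFrame, spec: ModelSpec, encoding: str = "abc_wyk"
) -> pd.DataFrame:
    """Sequential R² and adjusted-R² increments per term group.

    Groups are added in the spec's canonical order; each increment is the
    change relative to the model with all preceding groups.
    """
    rows = []
    prev_r2, prev_adj = 0.0, 0.0
    groups_so_far: list[str] = []
    for g in spec.groups:
        groups_so_far.append(g)
        fit = fit_model(table, ModelSpec(tuple(groups_so_far)), encoding)
        if g == "INTERCEPT":
            prev_r2, prev_adj = fit.r2_, fit.adj_r2_
            continue
        rows.append(
            {
                "group": g,
                "n_columns": len(TERM_GROUPS[g]),
                "r2_increment": fit.r2_ - prev_r2,
                "adj_r2_increment": fit.adj_r2_ - prev_adj,
                "r2_cumulative": fit.r2_,
                "adj_r2_cumulative": fit.adj_r2_,
            }
        )
        prev_r2, prev_adj = fit.r2_, fit.adj_r2_
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Energy logos
# ---------------------------------------------------------------------------

_NUCS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class EnergyLogo:
    """Numeric energy-logo matrix for one protein.

    ``table`` has one row per state/combination with columns: ``column``
    (site3 | site4 | epistasis), ``state``, ``height`` (kcal/mol, deviation
    from the protein's mean over REs), ``width`` (adjusted-R² share of the
    column's term group, floored at 0), ``star`` (Bonferroni-corrected LRT
    significance).  Rows are ranked by |height| within each column.
    """

    protein: str
    table: pd.DataFrame
    family_size: int | None = None


def logo_comparisons(
    table: pd.DataFrame, encoding: str = "abc_wyk", family_size: int = 3
) -> dict[str, NestedComparison]:
    """The three per-protein LRTs behind logo stars.

    Site 3 is tested by adding its first-order terms to a site-4-only
    model (and vice versa); the epistasis column by adding the pairwise
    terms to the full first-order RE model.
    """
    i = ModelSpec(("INTERCEPT",))
    f3 = fit_model(table, i.with_groups("R1_3"), encoding)
    f4 = fit_model(table, i.with_groups("R1_4"), encoding)
    f34 = fit_model(table, i.with_groups("R1_3", "R1_4"), encoding)
    f_full = fit_model(table, i.with_groups("R1_3", "R1_4", "R2"), encoding)
    return {
        "site3": compare_nested(f4, f34, family_size),
        "site4": compare_nested(f3, f34, family_size),
        "epistasis": compare_nested(f34, f_full, family_size),
    }


def build_energy_logo(
    fit: EpistasisRegression,
    comparisons: dict[str, NestedComparison] | None = None,
    widths: dict[str, float] | None = None,
    protein: str = "",
    alpha: float = 0.05,
) -> EnergyLogo:
    """Assemble the logo matrix from a fitted {R1_3, R1_4, R2} model.

    ``widths`` are the adjusted-R² increments per column (computed from
    ``comparisons``' nesting when not given); stars require
    ``comparisons`` — without them widths are still emitted and stars are
    omitted with a warning.
    """
    fit._require_groups("R1_3", "R1_4", "R2")
    if comparisons is None:
        logger.warning("no nested comparisons supplied; logo stars omitted")
    rows = []
    for column, states, height_fn in (
        ("site3", _NUCS, lambda s: fit.state_effect(3, s)),
        ("site4", _NUCS, lambda s: fit.state_effect(4, s)),
        (
            "epistasis",
            [a + b for a in _NUCS for b in _NUCS],
            lambda s: fit.pair_epistasis(s[0], s[1]),
        ),
    ):
        star = False
        if comparisons is not None and column in comparisons:
            star = comparisons[column].p_adjusted < alpha
        if widths is not None:
            width = widths.get(column, float("nan"))
        elif comparisons is not None and column in comparisons:
            width = comparisons[column].adj_r2_increment
        else:
            width = float("nan")
        width = max(0.0, width) if math.isfinite(width) else width
        heights = sorted(
            ((s, height_fn(s)) for s in states),
            key=lambda kv: -abs(kv[1]),
        )
        for s, h in heights:
            rows.append(
                {
                    "column": column,
                    "state": s,
                    "height": h,
                    "width": width,
                    "star": star if comparisons is not None else None,
                }
            )
    fam = comparisons and next(iter(comparisons.values())).family_size
    return EnergyLogo(protein=protein, table=pd.DataFrame(rows), family_size=fam)


def energy_logo_for_protein(
    table: pd.DataFrame,
    protein: str,
    encoding: str = "abc_wyk",
    alpha: float = 0.05,
    family_size: int = 3,
) -> EnergyLogo:
    """Full logo pipeline for one protein's rows of a measurement table.

    Widths are the sequential adjusted-R² increments (site 3, then site 4,
    then pairwise epistasis); stars come from the per-column LRTs of
    :func:`logo_comparisons`.
    """
    sub = table[table["protein"] == protein]
    if sub.empty:
        raise ValueError(f"no measurements for protein {protein!r}")
    fit = fit_model(sub, RE_SPEC, encoding)
    comps = logo_comparisons(sub, encoding, family_size)
    vp = variance_partition(sub, RE_SPEC, encoding).set_index("group")
    widths = {
        "site3": float(vp.loc["R1_3", "adj_r2_increment"]),
        "site4": float(vp.loc["R1_4", "adj_r2_increment"]),
        "epistasis": float(vp.loc["R2", "adj_r2_increment"]),
    }
    return build_energy_logo(
        fit, comps, widths=widths, protein=protein, alpha=alpha
    )
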