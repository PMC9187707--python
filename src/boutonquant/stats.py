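"""Mixed-model ANOVA of site-level CB1R means, with Bonferroni post-hocs.

The dependent measure is the per-(site, cell type) mean CB1R intensity.
Brain region, cell type and their interaction enter as fixed effects
(sum-to-zero coding, so the Wald F tests are the Type III ANOVA tests) and
subject as a random intercept; each species is analysed separately.  The
post-hoc decomposition mirrors the study's reporting: simple-effect F of
region within each cell type, then pairwise region contrasts within cell
type, Bonferroni-corrected within family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InvalidParameterError
from .mixed import RandomInterceptFit, fit_random_intercept, wald_f

CELL_TYPES = ("vglut1", "vgat")


@dataclass
class EffectTest:
    F: float
    df_num: int
    df_den: float
    p: float
    df_den_satterthwaite: float | None = None
    p_satterthwaite: float | None = None


@dataclass
class AnovaResult:
    species: str
    effects: dict[str, EffectTest]
    random_subject_variance: float
    residual_variance: float
    n_rows: int
    regions: tuple[str, ...]
    cell_types: tuple[str, ...]
    fit: RandomInterceptFit = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_rows": self.n_rows,
            "random_subject_variance": self.random_subject_variance,
            "residual_variance": self.residual_variance,
            "effects": {
                name: {
                    "F": t.F, "df_num": t.df_num, "df_den": t.df_den, "p": t.p,
                    "df_den_satterthwaite": t.df_den_satterthwaite,
                    "p_satterthwaite": t.p_satterthwaite,
                }
                for name, t in self.effects.items()
            },
        }


def _design_matrix(rows: pd.DataFrame, regions: tuple[str, ...],
                   cell_types: tuple[str, ...]):
    """Sum-to-zero-coded design: intercept | region | cell type | interaction.

    Returns (X, column blocks) where blocks maps effect name -> column index
    array.
    """
    k = len(regions)
    reg_idx = rows["region"].map({r: i for i, r in enumerate(regions)}).to_numpy()
    typ_idx = rows["bouton_type"].map({t: i for i, t in enumerate(cell_types)}).to_numpy()
    n = len(rows)
    # sum-to-zero region columns: levels 0..k-2 get +1, last level gets -1
    R = np.zeros((n, k - 1))
    for j in range(k - 1):
        R[reg_idx == j, j] = 1.0
    R[reg_idx == k - 1, :] = -1.0
    c = np.where(typ_idx == 0, 1.0, -1.0)[:, None]
    X = np.hstack([np.ones((n, 1)), R, c, R * c])
    blocks = {
        "region": np.arange(1, k),
        "cell_type": np.array([k]),
        "cell_type:region": np.arange(k + 1, 2 * k),
    }
    return X, blocks


def _cell_mean_row(region: str, cell_type: str, regions: tuple[str, ...],
                   cell_types: tuple[str, ...]) -> np.ndarray:
    """Design row whose dot with beta is the (cell type, region) cell mean."""
    k = len(regions)
    x = np.zeros(2 * k)
    x[0] = 1.0
    j = regions.index(region)
    r = np.zeros(k - 1)
    if j < k - 1:
        r[j] = 1.0
    else:
        r[:] = -1.0
    c = 1.0 if cell_type == cell_types[0] else -1.0
    x[1:k] = r
    x[k] = c
    x[k + 1:] = r * c
    return x


def fit_mixed_anova(site_rows: pd.DataFrame, species: str,
                    df_method: str = "residual",
                    with_satterthwaite: bool = True,
                    fix_lambda: float | None = None) -> AnovaResult:
    """Fit the region × cell-type mixed ANOVA for one species.

    ``site_rows`` needs columns site_id, subject, species, region,
    bouton_type, mean_cb1r_adu (the sites.csv shape).
    """
    rows = site_rows[site_rows["species"] == species].reset_index(drop=True)
    if rows.empty:
        raise DegenerateDesignError(f"no rows for species {species!r}")
    regions = tuple(dict.fromkeys(rows["region"]))
    cell_types = tuple(t for t in CELL_TYPES if t in set(rows["bouton_type"]))
    if rows["subject"].nunique() < 2:
        raise DegenerateDesignError("mixed ANOVA needs at least 2 subjects")
    if len(cell_types) < 2:
        raise DegenerateDesignError("both cell types must be present")
    if len(regions) < 2:
        raise DegenerateDesignError("at least 2 regions are required")
    cells = rows.groupby(["region", "bouton_type"]).size()
    if len(cells) < len(regions) * len(cell_types):
        warnings.warn("empty design cells; fit proceeds but estimates may be "
                      "poorly determined", stacklevel=2)

    X, blocks = _design_matrix(rows, regions, cell_types)
    fit = fit_random_intercept(rows["mean_cb1r_adu"].to_numpy(), X,
                               rows["subject"].to_numpy(), fix_lambda=fix_lambda)
    effects = {}
    for name, cols in blocks.items():
        L = np.zeros((len(cols), X.shape[1]))
        L[np.arange(len(cols)), cols] = 1.0
        F, q, dfd, p = wald_f(fit, L, df_method=df_method)
        test = EffectTest(F=F, df_num=q, df_den=dfd, p=p)
        if with_satterthwaite:
            _, _, dfd_s, p_s = wald_f(fit, L, df_method="satterthwaite")
            test.df_den_satterthwaite, test.p_satterthwaite = dfd_s, p_s
        effects[name] = test
    return AnovaResult(
        species=species, effects=effects,
        random_subject_variance=fit.sigma2_subject,
        residual_variance=fit.sigma2_residual,
        n_rows=len(rows), regions=regions, cell_types=cell_types, fit=fit,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` per value."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise InvalidParameterError("family size m must be >= number of p-values")
    return np.minimum(1.0, m_eff * p)


def posthoc_decomposition(result: AnovaResult, df_method: str = "residual") -> pd.DataFrame:
    """Simple effects of region within cell type, plus pairwise contrasts.

    Two families, Bonferroni-corrected within family: the simple-effect F
    tests (one per cell type, m = number of cell types) and, within each cell
    type, all pairwise region contrasts (m = number of pairs).
    """
    if "cell_type:region" not in result.effects:
        raise DegenerateDesignError("post-hoc decomposition requires the fitted "
                                    "interaction model")
    fit = result.fit
    regions, cell_types = result.regions, result.cell_types
    rows = []
    # family 1: simple-effect F of region within each cell type
    simple_ps = []
    for t in cell_types:
        base = _cell_mean_row(regions[-1], t, regions, cell_types)
        L = np.array([_cell_mean_row(r, t, regions, cell_types) - base
                      for r in regions[:-1]])
        F, q, dfd, p = wald_f(fit, L, df_method=df_method)
        simple_ps.append(p)
        rows.append({"family": "simple_effect", "cell_type": t,
                     "contrast": "region", "estimate": np.nan,
                     "F": F, "df_num": q, "df_den": dfd, "p_raw": p,
                     "m": len(cell_types)})
    adj = bonferroni(simple_ps, len(cell_types))
    for i in range(len(cell_types)):
        rows[i]["p_bonferroni"] = adj[i]
    # family 2: pairwise region contrasts within each cell type
    pairs = [(a, b) for i, a in enumerate(regions) for b in regions[i + 1:]]
    for t in cell_types:
        ps, idx0 = [], len(rows)
        for a, b in pairs:
            ell = (_cell_mean_row(a, t, regions, cell_types)
                   - _cell_mean_row(b, t, regions, cell_types))
            F, q, dfd, p = wald_f(fit, ell, df_method=df_method)
            est = float(ell @ fit.beta)
            ps.append(p)
            rows.append({"family": "pairwise", "cell_type": t,
                         "contrast": f"{a}-{b}", "estimate": est,
                         "F": F, "df_num": q, "df_den": dfd, "p_raw": p,
                         "m": len(pairs)})
        adj = bonferroni(ps, len(pairs))
        for i, a in enumerate(adj):
            rows[idx0 + i]["p_bonferroni"] = a
    return pd.DataFrame(rows)


def _fmt_p(p: float) -> str:
    return "p < 0.001" if p < 0.001 else f"p = {p:.3f}"


def report_text(result: AnovaResult, posthoc: pd.DataFrame | None = None) -> str:
    """Plain-text report in the field's F(a, b) = x reporting style."""
    lines = [f"Species: {result.species} (n = {result.n_rows} site x cell-type rows)"]
    names = {"cell_type": "main effect of cell type",
             "region": "main effect of brain region",
             "cell_type:region": "cell type x brain region interaction"}
    for key, label in names.items():
        t = result.effects[key]
        lines.append(f"  {label}, F({t.df_num},{t.df_den:.0f}) = {t.F:.3f}, {_fmt_p(t.p)}")
    lines.append(f"  random subject variance = {result.random_subject_variance:.1f}, "
                 f"residual variance = {result.residual_variance:.1f}")
    if posthoc is not None:
        lines.append("  post hoc (Bonferroni):")
        for _, r in posthoc.iterrows():
            if r["family"] == "simple_effect":
                lines.append(f"    region within {r['cell_type']}: "
                             f"F({r['df_num']},{r['df_den']:.0f}) = {r['F']:.3f}, "
                             f"adj {_fmt_p(r['p_bonferroni'])}")
            else:
                lines.append(f"    {r['cell_type']} {r['contrast']}: "
                             f"diff = {r['estimate']:.1f} ADU, adj {_fmt_p(r['p_bonferroni'])}")
    return "\n".join(lines)
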