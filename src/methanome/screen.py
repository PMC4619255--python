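"""Two-stage gene selection: per-KO GLM screen, then PLS with VIP pruning.

Stage 1 fits, for each KEGG orthologue separately, an ordinary least-squares
model of methane yield on diet plus that one KO abundance; KOs whose gene
coefficient has P < 0.1 pass.  Breed is checked once beforehand and enters
the screen models only if it shows an effect (P <= 0.1) on methane yield on
its own.  Stage 2 fits a single standardized PLS model on all passers plus
two complementary diet indicator columns, computes VIP scores, removes
effects with VIP < 0.8, and refits once on the survivors — exactly one
pruning pass, with no further iteration even if the refit moves a few
effects below the cutoff again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import AnimalPanel
from .pls import PLSModel, VIPResult, pls_fit, vip

logger = logging.getLogger(__name__)

__all__ = ["GLMScreenResult", "GeneSelection", "glm_screen", "diet_indicators", "select_genes"]

_EPS = 1e-12


@dataclass(frozen=True)
class GLMScreenResult:
    ko_id: str
    beta: float
    p_gene: float
    passed: bool
    flagged: bool = False  # zero-variance or collinear with the design


@dataclass
class GeneSelection:
    screen: list[GLMScreenResult]
    first_model: PLSModel | None
    first_vip: VIPResult | None
    final_model: PLSModel | None
    final_vip: VIPResult | None
    retained: list[str] = field(default_factory=list)

    @property
    def screen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ko_id": [r.ko_id for r in self.screen],
                "beta_screen": [r.beta for r in self.screen],
                "p_screen": [r.p_gene for r in self.screen],
                "passed_screen": [r.passed for r in self.screen],
                "flagged": [r.flagged for r in self.screen],
            }
        ).set_index("ko_id")

    def selection_frame(self) -> pd.DataFrame:
        out = self.screen_frame.copy()
        for col, res in (("vip_first", self.first_vip), ("vip_final", self.final_vip)):
            series = res.vip if res is not None else pd.Series(dtype=float)
            out[col] = out.index.map(series.to_dict())
        out["retained"] = out.index.isin(self.retained)
        return out


def breed_is_informative(panel: AnimalPanel, threshold: float = 0.1) -> tuple[bool, float]:
    """One-off check: does breed alone show an effect on methane yield?"""
    y = panel.ch4().to_numpy()
    x = panel.indicator("breed", panel.animals["breed"].iloc[0]).to_numpy()
    if np.std(x) < _EPS:
        return False, 1.0
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    p = float(fit.pvalues[1])
    return p <= threshold, p


def glm_screen(
    ko_table: pd.DataFrame,
    panel: AnimalPanel,
    threshold: float = 0.1,
    breed_threshold: float = 0.1,
) -> list[GLMScreenResult]:
    """Per-KO least-squares screen of methane yield on diet + one KO at a time.

    ``ko_table`` is animals x KOs, indexed by animal_id.  Each KO's
    coefficient gets a two-sided t-test; ``passed`` means p < ``threshold``.
    Constant KO columns and KOs collinear with the base design are flagged
    and excluded from the pass set.
    """
    ids = panel.animal_ids
    missing = [a for a in ids if a not in ko_table.index]
    if missing:
        raise ValueError(f"ko_table missing animals {missing}")
    X_ko = ko_table.loc[ids]
    y = panel.ch4().loc[ids].to_numpy()

    base_cols = [np.ones(len(ids)), panel.indicator("diet", "Conc").loc[ids].to_numpy()]
    use_breed, p_breed = breed_is_informative(panel, breed_threshold)
    if use_breed:
        base_cols.append(panel.indicator("breed", "AA").loc[ids].to_numpy())
    logger.info(
        "breed pre-check: P = %.3f -> breed %s in screen models",
        p_breed, "included" if use_breed else "omitted",
    )
    base = np.column_stack(base_cols)
    base_rank = np.linalg.matrix_rank(base)

    results = []
    for ko in X_ko.columns:
        col = X_ko[ko].to_numpy(dtype=float)
        design = np.column_stack([base, col])
        if np.std(col, ddof=0) < _EPS or np.linalg.matrix_rank(design) <= base_rank:
            results.append(GLMScreenResult(str(ko), np.nan, np.nan, False, flagged=True))
            continue
        fit = sm.OLS(y, design).fit()
        beta = float(fit.params[-1])
        p = float(fit.pvalues[-1])
        results.append(GLMScreenResult(str(ko), beta, p, bool(p < threshold)))
    return results


def diet_indicators(panel: AnimalPanel) -> pd.DataFrame:
    """Two complementary 0/1 diet columns (centred later by the PLS scaling).

    Using both columns — exact complements — yields the symmetric +/-
    standardized estimates conventional for a two-level effect in PLS.
    """
    conc = panel.indicator("diet", "Conc")
    return pd.DataFrame({"Diet_Conc": conc, "Diet_Med": 1.0 - conc})


def select_genes(
    ko_table: pd.DataFrame,
    panel: AnimalPanel,
    screen_threshold: float = 0.1,
    vip_cutoff: float = 0.8,
    n_factors: int | str = "auto",
    max_factors: int | None = 10,
) -> GeneSelection:
    """Full selection pipeline: GLM screen -> PLS -> VIP prune -> one refit.

    Diet indicator columns always accompany the screened KOs into the PLS
    stage.  Returns the screen results, both fitted models and VIP sets, and
    the final retained KO list (diet columns are reported in the VIPs but
    not listed under ``retained``).
    """
    screen = glm_screen(ko_table, panel, threshold=screen_threshold)
    passers = [r.ko_id for r in screen if r.passed]
    empty = GeneSelection(screen, None, None, None, None, [])
    if not passers:
        logger.info("no KO passed the screen at P < %.3g", screen_threshold)
        return empty

    ids = panel.animal_ids
    diet = diet_indicators(panel).loc[ids]
    X1 = pd.concat([ko_table.loc[ids, passers], diet], axis=1)
    y = panel.ch4().loc[ids]
    model1 = pls_fit(X1, y, n_factors=n_factors, max_factors=max_factors)
    vip1 = vip(model1, cutoff=vip_cutoff)

    survivors = vip1.retained_predictors
    if not survivors:
        return GeneSelection(screen, model1, vip1, None, None, [])
    X2 = X1[survivors]
    model2 = pls_fit(X2, y, n_factors=n_factors, max_factors=max_factors)
    vip2 = vip(model2, cutoff=vip_cutoff)
    retained = [k for k in survivors if k in set(passers)]
    return GeneSelection(screen, model1, vip1, model2, vip2, retained)
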