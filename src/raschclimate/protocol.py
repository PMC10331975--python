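"""Five-step validation protocol with iterative misfit-item removal.

Step 1  rating-scale functioning (monotone average measures, category outfit)
Step 2a local independence (residual correlations)
Step 2b item goodness-of-fit with a removal loop: the single worst item
        whose infit MnSq falls outside the acceptance interval is removed
        and the model refitted, until all remaining items fit
Step 2c unidimensionality (variance explained, first-contrast eigenvalue)
Step 3  person goodness-of-fit (flag rate against the 5% budget)
Step 4  precision/reliability (separation, reliability, floor/ceiling)
Step 5  differential item functioning (Mantel chi-square per factor)

Finally the raw-score mean-value index over the retained index items is
computed and correlated with the Rasch person measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io_model import AnalysisConfig, FactorTable, InputError, ResponseMatrix
from .rsm import EstimationSettings, RSMParameters, fit_jmle
from .fit import classify_item_fit, flag_persons, flag_rate, item_fit, person_fit
from .rating_scale import category_diagnostics
from .structure import pca_of_residuals
from .reliability import reliability
from .dif import dif_scan

__all__ = [
    "ProtocolReport",
    "IndexScores",
    "run_protocol",
    "mean_value_index",
    "index_measure_correlation",
]


@dataclass
class IndexScores:
    """Per-person benchmarking index over the index items.

    ``raw_mean`` is the plain mean of the 1..K+1 codes; ``scaled`` maps it
    affinely onto 0-100: scaled = (raw_mean - 1) / (n_categories - 1) * 100.
    """

    table: pd.DataFrame  # person-indexed: raw_mean, scaled, measure
    items: tuple[str, ...]


@dataclass
class ProtocolReport:
    steps: dict
    removed_items: list[dict]
    final_items: list[str]
    index_measure_r: float | None
    index_measure_p: float | None
    config: dict
    seed: int
    params: RSMParameters | None = None
    index_scores: IndexScores | None = None
    dif_table: pd.DataFrame | None = None

    def all_pass(self) -> bool:
        return all(s["passes"] for s in self.steps.values())

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "removed_items": self.removed_items,
            "final_items": self.final_items,
            "index_measure_r": self.index_measure_r,
            "index_measure_p": self.index_measure_p,
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True, default=_json_default)

    def render_text(self) -> str:
        lines = ["Validation protocol report", "=" * 60]
        for name, step in self.steps.items():
            verdict = "PASS" if step["passes"] else "FAIL"
            lines.append(f"[{verdict}] {name}: {step['criterion']}")
            for k, v in step.get("observed", {}).items():
                lines.append(f"         {k}: {_fmt(v)}")
        if self.removed_items:
            removed = ", ".join(
                f"{r['item']} (infit {r['infit_mnsq']:.2f}, pass {r['pass']})"
                for r in self.removed_items
            )
            lines.append(f"Removed items: {removed}")
        else:
            lines.append("Removed items: none")
        lines.append(f"Final item set: {', '.join(self.final_items)}")
        if self.index_measure_r is not None:
            lines.append(
                f"Index vs measure: r = {self.index_measure_r:.3f}"
                f" (p = {self.index_measure_p:.2g})"
            )
        return "\n".join(lines)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def mean_value_index(
    m: ResponseMatrix, items: list[str], params: RSMParameters | None = None
) -> IndexScores:
    """Raw mean-value index (1..K+1) and its 0-100 rescaling per person.

    Persons with missing responses on any index item are excluded.  When
    fitted parameters are supplied, each person's Rasch measure rides along
    for index-vs-measure comparison.
    """
    sub = m.subset_items(items)
    coded = sub.coded()
    complete = ~coded.mask.any(axis=1)
    raw_mean = sub.values.mean(axis=1)[complete]
    scaled = (raw_mean - 1.0) / (m.n_categories - 1) * 100.0
    persons = [p for p, ok in zip(m.persons, complete) if ok]
    data = {"raw_mean": raw_mean, "scaled": scaled}
    if params is not None:
        lookup = dict(zip(params.persons, params.theta))
        data["measure"] = [lookup[p] for p in persons]
    df = pd.DataFrame(data, index=pd.Index(persons, name="person"))
    return IndexScores(df, tuple(items))


def index_measure_correlation(
    idx: IndexScores,
    m: ResponseMatrix | None = None,
    exclude_floor: bool = True,
    exclude_ceiling: bool = False,
):
    """Pearson correlation between the 0-100 index and the Rasch measure.

    All-minimum (floor) patterns on the index items are excluded by default,
    mirroring the study's exclusion of its single floor participant;
    all-maximum (ceiling) exclusion is optional.
    """
    df = idx.table
    if "measure" not in df.columns:
        raise InputError("index scores carry no measures; fit the model first")
    keep = np.ones(len(df), dtype=bool)
    if exclude_floor:
        keep &= df["scaled"].to_numpy() > 0.0
    if exclude_ceiling:
        keep &= df["scaled"].to_numpy() < 100.0
    sub = df[keep]
    if len(sub) < 3:
        raise InputError("fewer than 3 persons after exclusions")
    if sub["scaled"].std() == 0 or sub["measure"].std() == 0:
        raise InputError("zero variance after exclusions; correlation undefined")
    r, p = pearsonr(sub["scaled"], sub["measure"])
    return float(r), float(p), int(len(sub))


def run_protocol(
    m: ResponseMatrix,
    factors: FactorTable | None = None,
    cfg: AnalysisConfig | None = None,
    settings: EstimationSettings | None = None,
) -> ProtocolReport:
    """Run the full five-step protocol with iterative item removal."""
    cfg = cfg or AnalysisConfig()
    settings = settings or EstimationSettings()
    steps: dict = {}
    removed: list[dict] = []

    current = m
    params = fit_jmle(current, settings)

    # Step 1: rating-scale functioning (on the full instrument)
    cat = category_diagnostics(current, params, cfg)
    steps["step1_rating_scale"] = {
        "criterion": (
            "average measures advance monotonically and category outfit "
            f"MnSq < {cfg.category_outfit_max}"
        ),
        "observed": {
            "monotonic": cat.monotonic,
            "max_category_outfit": float(np.nanmax(cat.table["outfit_mnsq"])),
            "category_counts": cat.table["count"].tolist(),
        },
        "passes": cat.passes,
    }

    # Step 2a: local independence (on the full instrument)
    structure_full = pca_of_residuals(current, params, cfg)
    a, b, r = structure_full.max_pair
    steps["step2a_local_independence"] = {
        "criterion": f"max |residual correlation| < {cfg.residual_corr_max}",
        "observed": {"max_pair": [a, b], "max_correlation": r},
        "passes": structure_full.local_independence_ok,
    }

    # Step 2b: item fit with removal loop
    pass_no = 0
    while True:
        pass_no += 1
        fit = item_fit(current, params)
        verdicts = classify_item_fit(fit, cfg)
        misfits = verdicts[verdicts == "misfit"].index
        if len(misfits) == 0:
            break
        infits = fit["infit_mnsq"][misfits]
        worst = (infits - 1.0).abs().idxmax()
        removed.append(
            {"item": worst, "infit_mnsq": float(fit["infit_mnsq"][worst]), "pass": pass_no}
        )
        remaining = [i for i in current.items if i != worst]
        if len(remaining) < 2:
            raise InputError("fewer than 2 items remain after misfit removal")
        current = current.subset_items(remaining)
        params = fit_jmle(current, settings)
    steps["step2b_item_fit"] = {
        "criterion": (
            f"all item infit MnSq within [{cfg.item_infit_lo}, {cfg.item_infit_hi}] "
            "after iterative removal"
        ),
        "observed": {
            "removed_items": [r_["item"] for r_ in removed],
            "max_infit": float(np.nanmax(fit["infit_mnsq"])),
            "min_infit": float(np.nanmin(fit["infit_mnsq"])),
        },
        "passes": True,
    }

    # Step 2c: unidimensionality on the retained set
    structure = pca_of_residuals(current, params, cfg)
    steps["step2c_unidimensionality"] = {
        "criterion": (
            f"variance explained >= {cfg.variance_explained_min}% and first "
            f"contrast eigenvalue < {cfg.first_contrast_eigen_max}"
        ),
        "observed": {
            "variance_explained_pct": structure.variance_explained_pct,
            "first_contrast_eigenvalue": structure.first_contrast_eigenvalue,
        },
        "passes": structure.unidimensional_ok,
    }

    # Step 3: person fit
    pfit = person_fit(current, params)
    rate = flag_rate(pfit, cfg)
    steps["step3_person_fit"] = {
        "criterion": (
            f"<= {cfg.person_misfit_budget:.0%} of persons with infit MnSq >= "
            f"{cfg.person_infit_max} and z >= {cfg.person_z_max}"
        ),
        "observed": {
            "flagged": int(flag_persons(pfit, cfg).sum()),
            "flag_rate_pct": 100.0 * rate,
        },
        "passes": bool(rate <= cfg.person_misfit_budget),
    }

    # Step 4: reliability / precision
    rel = reliability(current, params, cfg)
    steps["step4_reliability"] = {
        "criterion": (
            f"separation index >= {cfg.separation_min} and person reliability "
            f">= {cfg.reliability_min}"
        ),
        "observed": {
            "separation_index": rel.separation_index,
            "person_reliability": rel.person_reliability,
            "strata": rel.strata,
            "cronbach_alpha": rel.cronbach_alpha,
            "floor_pct": rel.floor_pct,
            "ceiling_pct": rel.ceiling_pct,
            "targeting_offset": rel.targeting_offset,
        },
        "passes": rel.passes,
    }

    # Step 5: DIF
    dif_table = None
    if factors is not None and factors.factor_names():
        dif = dif_scan(current, params, factors, cfg)
        dif_table = dif.table
        flagged = dif.flagged
        steps["step5_dif"] = {
            "criterion": (
                f"no Bonferroni-adjusted Mantel p < {cfg.dif_alpha} on any "
                "item × factor × group pair"
            ),
            "observed": {
                "n_tests": int(len(dif.table)),
                "n_flagged": int(len(flagged)),
                "flagged": flagged[["item", "factor", "group_a", "group_b", "p_adj"]]
                .to_dict("records"),
            },
            "passes": not dif.any_dif(),
        }
    else:
        steps["step5_dif"] = {
            "criterion": "no factor table supplied",
            "observed": {},
            "passes": True,
        }

    # Benchmarking index on the retained items
    index_items = (
        [i for i in cfg.index_items if i in current.items]
        if cfg.index_items is not None
        else list(current.items)
    )
    r_val = p_val = None
    idx = None
    if len(index_items) >= 2:
        idx = mean_value_index(m, index_items, params)
        try:
            r_val, p_val, _ = index_measure_correlation(
                idx, exclude_ceiling=cfg.exclude_ceiling_from_index_corr
            )
        except InputError:
            r_val = p_val = None

    return ProtocolReport(
        steps=steps,
        removed_items=removed,
        final_items=list(current.items),
        index_measure_r=r_val,
        index_measure_p=p_val,
        config=cfg.to_dict(),
        seed=cfg.random_seed,
        params=params,
        index_scores=idx,
        dif_table=dif_table,
    )
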