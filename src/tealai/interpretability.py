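"""Additive per-feature attribution of model predictions.

Every prediction is decomposed as f(x) = phi0 + sum_i phi_i(x) where phi0
is the expected model output over a background set (the training table by
default) and phi_i is feature i's contribution in LAI units. Three exact
routes are used, one per model structure:

* linear models: phi_i = coef_i * (x_i - mean(x_i)) over the background,
  the closed-form Shapley value of a linear model;
* decision trees and forests: exact tree-path decomposition — walking each
  sample's decision path, the change in node mean value at every split is
  attributed to the split feature (forests average over trees);
* gradient-boosted trees: the same path decomposition applied to the
  booster's dumped trees (internal-node expected values are cover-weighted
  averages of their children), evaluated in double precision.

Additivity holds to numerical precision for all three, and global
importance is the mean absolute contribution per feature, descending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .features import FEATURE_COLUMNS, FeatureTable

__all__ = ["AttributionSet", "attribute", "global_importance"]


@dataclass
class AttributionSet:
    """Additive attributions: phi0 + row-sum of phi = model prediction."""

    phi0: float
    phi: pd.DataFrame          # samples x features, LAI units
    predictions: pd.Series     # model predictions on the attributed rows

    def additivity_gap(self) -> float:
        """Max |phi0 + sum_i phi_i - prediction| across samples."""
        recon = self.phi0 + self.phi.sum(axis=1)
        return float(np.max(np.abs(recon - self.predictions)))

    def tidy(self) -> pd.DataFrame:
        """Long-format (sample, feature, phi) table for beeswarm-style use."""
        out = self.phi.stack().rename("phi").reset_index()
        out.columns = ["sample_id", "feature", "phi"]
        return out


def _tree_path_contribs(estimator, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact path attribution for one fitted sklearn regression tree."""
    t = estimator.tree_
    values = t.value.reshape(t.node_count, -1)[:, 0]
    phi = np.zeros((x.shape[0], x.shape[1]))
    paths = estimator.decision_path(x)
    indptr, indices = paths.indptr, paths.indices
    for row in range(x.shape[0]):
        nodes = indices[indptr[row]: indptr[row + 1]]
        for parent, child in zip(nodes[:-1], nodes[1:]):
            phi[row, t.feature[parent]] += values[child] - values[parent]
    return float(values[0]), phi


def _xgb_node_values(node: dict, values: dict) -> tuple[float, float]:
    """Recursively fill expected node values (cover-weighted child means).

    Returns (expected value, cover) of ``node``."""
    if "leaf" in node:
        values[node["nodeid"]] = float(node["leaf"])
        return float(node["leaf"]), float(node["cover"])
    (vl, cl), (vr, cr) = (_xgb_node_values(ch, values)
                          for ch in node["children"])
    v = (vl * cl + vr * cr) / (cl + cr)
    values[node["nodeid"]] = v
    return v, float(node["cover"])


def _xgb_path_contribs(booster, x: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Path attribution for a fitted gradient-boosting booster, in float64.

    Walks every tree of the dumped model; each split's change in expected
    node value is credited to the split feature. phi0 is the base score
    plus the sum of the trees' root expectations. Also returns the model
    predictions recomputed in double precision as base score + sum of
    traversed leaf values (the additive-ensemble definition), independent
    of the contribution bookkeeping.
    """
    import json

    config = json.loads(booster.save_config())
    base = float(config["learner"]["learner_model_param"]["base_score"])
    phi = np.zeros_like(x, dtype=float)
    preds = np.full(x.shape[0], base, dtype=float)
    phi0 = base
    for dump in booster.get_dump(dump_format="json", with_stats=True):
        root = json.loads(dump)
        values: dict[int, float] = {}
        root_value, _ = _xgb_node_values(root, values)
        phi0 += root_value
        for row in range(x.shape[0]):
            node = root
            while "leaf" not in node:
                feat = int(node["split"].lstrip("f"))
                xv = x[row, feat]
                if np.isnan(xv):
                    nxt = node["missing"]
                else:
                    # the booster stores data and thresholds in float32
                    go_left = np.float32(xv) < np.float32(node["split_condition"])
                    nxt = node["yes"] if go_left else node["no"]
                child = next(ch for ch in node["children"]
                             if ch["nodeid"] == nxt)
                phi[row, feat] += values[child["nodeid"]] - values[node["nodeid"]]
                node = child
            preds[row] += float(node["leaf"])
    return phi0, phi, preds


def attribute(estimator, table: FeatureTable,
              background: FeatureTable | None = None) -> AttributionSet:
    """Decompose ``estimator`` predictions on ``table`` into additive phis.

    ``background`` fixes the reference distribution defining phi0 (training
    table by default, i.e. ``table`` itself). The table must carry the same
    61-feature ordering the estimator was fitted on.
    """
    x = table.features.to_numpy(dtype=float)
    n_in = getattr(estimator, "n_features_in_", x.shape[1])
    if n_in != x.shape[1]:
        raise ValueError(
            f"estimator was fitted on {n_in} features, table has {x.shape[1]}")
    index = table.data.index
    preds = pd.Series(np.asarray(estimator.predict(x), dtype=float).ravel(),
                      index=index)
    bg = x if background is None else background.features.to_numpy(dtype=float)

    if isinstance(estimator, LinearRegression):
        mean = bg.mean(axis=0)
        phi = estimator.coef_ * (x - mean)
        phi0 = float(estimator.intercept_ + estimator.coef_ @ mean)
    elif isinstance(estimator, DecisionTreeRegressor):
        phi0, phi = _tree_path_contribs(estimator, x)
    elif isinstance(estimator, RandomForestRegressor):
        phi = np.zeros_like(x)
        phi0 = 0.0
        for tree in estimator.estimators_:
            root, contrib = _tree_path_contribs(tree, x)
            phi += contrib
            phi0 += root
        phi /= len(estimator.estimators_)
        phi0 /= len(estimator.estimators_)
    elif isinstance(estimator, XGBRegressor):
        phi0, phi, pred64 = _xgb_path_contribs(estimator.get_booster(), x)
        # Double-precision re-evaluation of the fitted trees; the booster's
        # own predict() agrees up to float32 output rounding.
        if np.max(np.abs(pred64 - preds)) > 1e-4:
            raise AssertionError("tree-walk predictions diverge from booster")
        preds = pd.Series(pred64, index=index)
    else:
        raise TypeError(f"unsupported estimator type {type(estimator).__name__}")

    phi_df = pd.DataFrame(phi, index=index, columns=list(FEATURE_COLUMNS))
    return AttributionSet(phi0=phi0, phi=phi_df, predictions=preds)


def global_importance(attributions: AttributionSet) -> pd.Series:
    """Features ranked by mean |phi| descending; ties ordered by name."""
    if attributions.phi.empty:
        raise ValueError("empty attribution set")
    imp = attributions.phi.abs().mean(axis=0)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order].rename("mean_abs_phi")
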