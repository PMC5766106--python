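"""Hierarchical (multi-block) PCA for sensor groups of very different width.

A current profiler contributes tens of depth-bin variables while a
fluorometer contributes one; thrown into a single PCA the profiler block
would dominate and the loading plot would drown.  The multi-block model
therefore fits one PCA per wide block, keeps a few block score vectors as
summary variables, and fits a *super* PCA on those score columns joined with
the individual sensor variables.  Everything is autoscaled at both levels, so
each of the super-variables enters with unit calibration variance.

New raw observations are projected end-to-end: block variables through their
sub-model (missing-aware), the assembled super-vector through the super
model.  T²/Q monitoring runs at the super level; block-level Q is retained
for drill-down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .pca import NipalsPCA, as_frame

__all__ = ["BlockSpec", "MultiblockPCA", "fit_multiblock"]

_SCHEMA_VERSION = 1


@dataclass
class BlockSpec:
    """Assignment of variables to blocks.

    ``blocks`` maps a block name to its variable labels; ``block_components``
    the number of sub-model components per block (int applies to all blocks);
    ``individual_variables`` are fed directly to the super model.  If
    ``individual_variables`` is None it defaults, at validation time, to all
    table variables not claimed by a block.
    """

    blocks: Mapping[str, Sequence[str]]
    block_components: int | Mapping[str, int] = 3
    individual_variables: Sequence[str] | None = None

    def components_for(self, block: str) -> int:
        if isinstance(self.block_components, Mapping):
            return int(self.block_components[block])
        return int(self.block_components)

    def resolve(self, variables: Sequence[str]) -> "BlockSpec":
        """Validate against table labels; fill in individual variables."""
        variables = list(variables)
        claimed: list[str] = []
        for name, members in self.blocks.items():
            members = list(members)
            if len(members) == 0:
                raise ValueError(f"block {name!r} is empty")
            unknown = [v for v in members if v not in variables]
            if unknown:
                raise ValueError(f"block {name!r}: unknown variables {unknown}")
            claimed += members
        if len(set(claimed)) != len(claimed):
            dup = sorted({v for v in claimed if claimed.count(v) > 1})
            raise ValueError(f"variables assigned to more than one block: {dup}")
        if self.individual_variables is None:
            individual = [v for v in variables if v not in set(claimed)]
        else:
            individual = list(self.individual_variables)
            unknown = [v for v in individual if v not in variables]
            if unknown:
                raise ValueError(f"unknown individual variables: {unknown}")
            overlap = sorted(set(individual) & set(claimed))
            if overlap:
                raise ValueError(
                    f"variables both individual and in a block: {overlap}")
        return BlockSpec(blocks={k: list(v) for k, v in self.blocks.items()},
                         block_components=self.block_components,
                         individual_variables=individual)


class MultiblockPCA(TransformerMixin, BaseEstimator):
    """Two-level PCA: per-block sub-models plus an autoscaled super model.

    Parameters
    ----------
    blocks : mapping of block name -> variable labels
    block_components : int or mapping, default 3
        Sub-model components per block.
    n_components : int, default 4
        Components of the super model.
    individual_variables : sequence of str, optional
        Variables entering the super model directly; defaults to every
        variable not claimed by a block.
    scale, tol, max_iter : forwarded to the underlying :class:`NipalsPCA`.

    Attributes
    ----------
    block_models_ : dict of NipalsPCA
    super_model_ : NipalsPCA fitted on the assembled super-matrix
    super_variable_labels_ : e.g. ``[... , "aquadopp_PC1", ...]``
    """

    def __init__(self, blocks: Mapping[str, Sequence[str]] | None = None,
                 block_components: int | Mapping[str, int] = 3,
                 n_components: int = 4,
                 individual_variables: Sequence[str] | None = None,
                 scale: bool = True, tol: float = 1e-10, max_iter: int = 5000):
        self.blocks = blocks
        self.block_components = block_components
        self.n_components = n_components
        self.individual_variables = individual_variables
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    # ---------------------------------------------------------------- fit
    def fit(self, X, y=None) -> "MultiblockPCA":
        frame = as_frame(X)
        if not self.blocks:
            raise ValueError("MultiblockPCA needs at least one block")
        spec = BlockSpec(self.blocks, self.block_components,
                         self.individual_variables).resolve(frame.columns)
        self.spec_ = spec
        self.block_models_ = {}
        score_cols: dict[str, np.ndarray] = {}
        for name, members in spec.blocks.items():
            sub = NipalsPCA(n_components=spec.components_for(name),
                            scale=self.scale, tol=self.tol,
                            max_iter=self.max_iter)
            try:
                sub.fit(frame[members])
            except ValueError as exc:
                raise ValueError(f"block {name!r}: {exc}") from exc
            self.block_models_[name] = sub
            for a in range(sub.n_components_):
                score_cols[f"{name}_PC{a + 1}"] = sub.scores_[:, a]
        super_frame = pd.concat(
            [frame[spec.individual_variables],
             pd.DataFrame(score_cols, index=frame.index)], axis=1)
        self.super_model_ = NipalsPCA(n_components=self.n_components,
                                      scale=self.scale, tol=self.tol,
                                      max_iter=self.max_iter).fit(super_frame)
        self.super_variable_labels_ = list(super_frame.columns)
        self.feature_names_in_ = [str(c) for c in frame.columns]
        self.n_features_in_ = frame.shape[1]
        # delegate the monitoring surface to the super model
        sm = self.super_model_
        self.n_samples_ = sm.n_samples_
        self.n_components_ = sm.n_components_
        self.components_ = sm.components_
        self.scores_ = sm.scores_
        self.score_variances_ = sm.score_variances_
        self.explained_variance_ratio_ = sm.explained_variance_ratio_
        self.residual_eigenvalues_ = sm.residual_eigenvalues_
        return self

    @property
    def monitored_variables_(self) -> list[str]:
        return self.super_variable_labels_

    # ------------------------------------------------------------ project
    def _assemble(self, X) -> pd.DataFrame:
        """Raw observations -> super-matrix (individual vars + block scores).

        An observation whose entire block is missing cannot be summarised:
        its block-score cells (hence, downstream, its super score) are NaN.
        """
        frame = as_frame(X)
        have = set(map(str, frame.columns))
        needed = set(self.feature_names_in_)
        missing = sorted(needed - have)
        if missing:
            raise ValueError(f"observations lack model variables: {missing}")
        spec = self.spec_
        parts = [frame[spec.individual_variables]]
        for name, members in spec.blocks.items():
            sub = self.block_models_[name]
            scores, _ = sub.project(frame[members])
            whole_block_missing = frame[members].isna().all(axis=1).to_numpy()
            scores[whole_block_missing] = np.nan
            parts.append(pd.DataFrame(
                scores, index=frame.index,
                columns=[f"{name}_PC{a + 1}" for a in range(sub.n_components_)]))
        return pd.concat(parts, axis=1)

    def _preprocess(self, X) -> tuple[np.ndarray, pd.Index]:
        return self.super_model_._preprocess(self._assemble(X))

    def project(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Super-level scores and residuals for raw observations.

        An observation missing an entire block is flagged, not scored
        (NaN scores and residuals).
        """
        frame = as_frame(X)
        scores, residuals = self.super_model_.project(self._assemble(frame))
        unsummarisable = np.zeros(len(frame), dtype=bool)
        for members in self.spec_.blocks.values():
            unsummarisable |= frame[members].isna().all(axis=1).to_numpy()
        scores[unsummarisable] = np.nan
        residuals[unsummarisable] = np.nan
        return scores, residuals

    def project_detailed(self, X) -> dict[str, Any]:
        """End-to-end projection with block-level drill-down.

        Returns super scores/residuals plus, per block, sub-model scores and
        Q-residuals (sub-level Q is reported but does not gate the alarm).
        """
        from .mspc import q_residuals

        frame = as_frame(X)
        out: dict[str, Any] = {}
        block_scores = {}
        block_q = {}
        for name, members in self.spec_.blocks.items():
            sub = self.block_models_[name]
            s, r = sub.project(frame[members])
            block_scores[name] = s
            block_q[name] = q_residuals(r)
        scores, residuals = self.project(frame)
        out["super_scores"] = scores
        out["super_residuals"] = residuals
        out["block_scores"] = block_scores
        out["block_q"] = block_q
        return out

    def transform(self, X) -> np.ndarray:
        return self.project(X)[0]

    # ------------------------------------------------------ serialization
    def to_dict(self) -> dict[str, Any]:
        params = self.get_params()
        params["blocks"] = {k: list(v) for k, v in self.spec_.blocks.items()}
        params["individual_variables"] = list(self.spec_.individual_variables)
        if isinstance(params["block_components"], Mapping):
            params["block_components"] = dict(params["block_components"])
        return {
            "schema_version": _SCHEMA_VERSION,
            "kind": "MultiblockPCA",
            "params": params,
            "feature_names": self.feature_names_in_,
            "super_variable_labels": self.super_variable_labels_,
            "block_models": {k: m.to_dict() for k, m in self.block_models_.items()},
            "super_model": self.super_model_.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MultiblockPCA":
        if d.get("kind") != "MultiblockPCA" or d.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError("not a MultiblockPCA model file (or wrong schema version)")
        model = cls(**d["params"])
        model.spec_ = BlockSpec(d["params"]["blocks"],
                                d["params"]["block_components"],
                                d["params"]["individual_variables"]).resolve(
            d["feature_names"])
        model.feature_names_in_ = list(d["feature_names"])
        model.n_features_in_ = len(model.feature_names_in_)
        model.block_models_ = {k: NipalsPCA.from_dict(v)
                               for k, v in d["block_models"].items()}
        model.super_model_ = NipalsPCA.from_dict(d["super_model"])
        model.super_variable_labels_ = list(d["super_variable_labels"])
        sm = model.super_model_
        model.n_samples_ = sm.n_samples_
        model.n_components_ = sm.n_components_
        model.components_ = sm.components_
        model.score_variances_ = sm.score_variances_
        model.explained_variance_ratio_ = sm.explained_variance_ratio_
        model.residual_eigenvalues_ = sm.residual_eigenvalues_
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MultiblockPCA":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_multiblock(data, spec: BlockSpec, super_components: int = 4,
                   **kwargs) -> MultiblockPCA:
    """Functional wrapper mirroring :func:`seamspc.pca.fit_pca`."""
    return MultiblockPCA(blocks=spec.blocks,
                         block_components=spec.block_components,
                         n_components=super_components,
                         individual_variables=spec.individual_variables,
                         **kwargs).fit(data)
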