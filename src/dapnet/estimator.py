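"""Scikit-learn-style estimator running the full DAP detection pipeline.

:class:`DAPFinder` is fit on a samples × genes matrix ``X`` with a two-class
label vector ``y`` (or directly on an :class:`~dapnet.io.ExpressionDataset`).
The pipeline is: gene filtering (CV / minimum sample size) → univariate
outlier flagging → per-class association estimation → one-sample Fisher
Z-tests (Pearson) → two-sample Fisher Z-tests (non-MI metrics) → optional
permutation phase on a selected pair subset → per-family multiple-testing
adjustment. Fitted results live in ``records_`` (list of DapRecord),
``results_`` (the comprehensive table as a DataFrame) and ``report_``.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import association, inference, io, multitest, preprocess


class DAPFinder(BaseEstimator):
    """Detect differentially associated gene pairs between two phenotypes.

    Parameters
    ----------
    metric : {'pearson', 'spearman', 'kendall', 'mi'}
        Association metric estimated within each class.
    filter_config : preprocess.FilterConfig or None
        Gene filtering and outlier flagging; None means defaults (no CV
        filter, min 4 samples per class, no outlier flagging).
    permutation_config : inference.PermutationConfig or None
        None disables the permutation phase. Mutual information has no
        analytic test, so ``metric='mi'`` requires a permutation config.
    selection_config : inference.PairSelectionConfig or None
        Which pairs enter the permutation phase (default: all tested pairs).
    adjust_method : {'none', 'bh', 'qvalue', 'bonferroni', 'holm', 'hochberg'}
        Multiple-testing adjustment, applied separately to the two-sample
        Z-test family and the permutation family.
    pairs : io.GenePairList or None
        Restrict testing to these pairs; None tests all pairs.
    top10 : bool
        Include top-10 result tables in the run report.

    Attributes
    ----------
    records_ : list of io.DapRecord
    results_ : pandas.DataFrame (comprehensive table, deterministic order)
    report_ : io.RunReport
    classes_ : the two phenotype labels
    n_features_in_ : number of genes seen during fit
    """

    def __init__(
        self,
        metric: str = "pearson",
        filter_config=None,
        permutation_config=None,
        selection_config=None,
        adjust_method: str = "bh",
        pairs=None,
        top10: bool = True,
    ):
        self.metric = metric
        self.filter_config = filter_config
        self.permutation_config = permutation_config
        self.selection_config = selection_config
        self.adjust_method = adjust_method
        self.pairs = pairs
        self.top10 = top10

    # -- fitting ---------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit on samples × genes ``X`` with labels ``y``, or on an
        ExpressionDataset (``y`` ignored)."""
        if isinstance(X, io.ExpressionDataset):
            dataset = X
        else:
            dataset = self._dataset_from_xy(X, y)
        dataset.require_two_classes()
        t0 = time.perf_counter()

        if self.metric not in association.METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.adjust_method not in multitest.ADJUST_METHODS:
            raise ValueError(f"unknown adjustment {self.adjust_method!r}")
        fcfg = self.filter_config or preprocess.FilterConfig()
        if self.metric == "mi" and self.permutation_config is None:
            raise ValueError(
                "mutual information has no analytic difference test; "
                "enable the permutation test"
            )

        # gene filtering
        if fcfg.cv_min is not None:
            retained = preprocess.cv_filter(dataset, fcfg.cv_min)
        else:
            retained = set(dataset.gene_ids)
        mask = fcfg.resolve_mask(dataset)

        # candidate pairs among retained genes
        pair_list = self.pairs if self.pairs is not None else association.all_pairs(dataset)
        candidate = io.GenePairList(
            [p for p in pair_list if p[0] in retained and p[1] in retained]
        )
        assoc, dropped = association.pairwise_associations(
            dataset, mask, candidate, self.metric, fcfg.min_n_per_class
        )

        records = []
        for (g1, g2), (e1, e2) in assoc.items():
            rec = io.DapRecord(
                gene1_id=g1,
                gene2_id=g2,
                gene1_annotation=dataset.annotation(g1),
                gene2_annotation=dataset.annotation(g2),
                metric=self.metric,
                assoc_class1=e1.value,
                assoc_class2=e2.value,
                n_eff_class1=e1.n_eff,
                n_eff_class2=e2.n_eff,
                delta=e1.value - e2.value,
            )
            if self.metric == "pearson":
                for est, stat_f, p_f in ((e1, "stat_class1", "p_class1"),
                                         (e2, "stat_class2", "p_class2")):
                    t = inference.one_sample_fisher_z(est)
                    if t is not None:
                        setattr(rec, stat_f, t.statistic)
                        setattr(rec, p_f, t.p)
            if self.metric != "mi":
                t = inference.two_sample_fisher_z(e1, e2)
                if t is not None:
                    rec.z_diff = t.statistic
                    rec.p_diff = t.p
            records.append(rec)
        records = io.sort_records(records)

        # permutation phase
        n_perm_pairs = 0
        if self.permutation_config is not None:
            scfg = self.selection_config or inference.PairSelectionConfig(mode="all")
            selected = set(inference.select_pairs_for_permutation(records, scfg).pairs)
            if not selected:
                io.logger.warning("pair selection is empty; permutation phase skipped")
            for rec in records:
                if rec.pair in selected:
                    t = inference.permutation_test_difference(
                        dataset, mask, rec.pair, self.metric, self.permutation_config
                    )
                    if t is not None:
                        rec.p_perm = t.p
                        n_perm_pairs += 1

        # per-family adjustment
        if self.adjust_method != "none":
            self._adjust_family(records, "p_diff", "p_diff_adj")
            self._adjust_family(records, "p_perm", "p_perm_adj")

        records = io.sort_records(records)
        wall = time.perf_counter() - t0
        self.records_ = records
        self.results_ = self._to_frame(records)
        self.classes_ = dataset.classes
        self.n_features_in_ = dataset.n_genes
        self.dataset_ = dataset
        self.outlier_mask_ = mask
        self.report_ = self._build_report(
            dataset, fcfg, retained, records, dropped, n_perm_pairs, wall
        )
        return self

    def _adjust_family(self, records, raw_field, adj_field):
        idx = [i for i, r in enumerate(records) if getattr(r, raw_field) is not None]
        if not idx:
            return
        raw = [getattr(records[i], raw_field) for i in idx]
        adj = multitest.adjust(raw, self.adjust_method)
        for i, a in zip(idx, adj):
            setattr(records[i], adj_field, float(a))

    @staticmethod
    def _dataset_from_xy(X, y) -> io.ExpressionDataset:
        if y is None:
            raise ValueError("y (two-class labels) is required when X is a matrix")
        if isinstance(X, pd.DataFrame):
            gene_ids = [str(c) for c in X.columns]
            sample_ids = [str(i) for i in X.index]
            values = X.to_numpy(dtype=float).T
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-D (samples x genes)")
            gene_ids = [f"g{j}" for j in range(X.shape[1])]
            sample_ids = [f"s{i}" for i in range(X.shape[0])]
            values = X.T
        return io.ExpressionDataset(
            gene_ids=gene_ids,
            sample_ids=sample_ids,
            class_labels=np.asarray(y),
            values=values,
        )

    @staticmethod
    def _to_frame(records) -> pd.DataFrame:
        rows = [{c: getattr(r, c) for c in io.RESULT_COLUMNS} for r in records]
        return pd.DataFrame(rows, columns=io.RESULT_COLUMNS)

    def _build_report(self, dataset, fcfg, retained, records, dropped, n_perm_pairs, wall):
        def _perm_key(r):
            return (r.p_perm is None, r.p_perm if r.p_perm is not None else 0.0,
                    r.gene1_id, r.gene2_id)

        top_perm = [r for r in records if r.p_perm is not None]
        top_perm = sorted(top_perm, key=_perm_key)[:10]
        return io.RunReport(
            settings={
                "metric": self.metric,
                "cv_min": fcfg.cv_min,
                "min_n_per_class": fcfg.min_n_per_class,
                "outlier_method": fcfg.outlier_method,
                "outlier_k": fcfg.outlier_k,
                "outlier_scope": fcfg.outlier_scope,
                "adjustment": self.adjust_method,
                "permutation": self.permutation_config is not None,
            },
            diagnostics={
                "missing_cells": int(dataset.missing_mask.sum()),
                "genes_input": dataset.n_genes,
                "genes_used": len(retained),
                "pairs_tested": len(records),
                "pairs_dropped_min_n": len(dropped),
                "pairs_permuted": n_perm_pairs,
                "wall_time_s": round(wall, 3),
            },
            top_z=records[:10],
            top_perm=top_perm,
            include_top10=self.top10,
        )

    # -- output ---------------------------------------------------------------

    def write_outputs(self, output_dir, weight_field: str = "delta") -> dict:
        """Write result table, Cytoscape edge list and HTML report; returns paths."""
        if not hasattr(self, "records_"):
            raise RuntimeError("fit the estimator before writing outputs")
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "results": out / "dapfinder_results.tsv",
            "edges": out / "dapfinder_edges.tsv",
            "report": out / "dapfinder_report.html",
        }
        io.write_result_table(self.records_, paths["results"])
        io.write_cytoscape_edges(self.records_, paths["edges"], weight_field)
        settings = dict(self.report_.settings)
        settings["output_directory"] = str(out)
        self.report_.settings = settings
        io.write_html_report(self.report_, paths["report"])
        return paths

    def significant_pairs(self, alpha: float = 0.05, family: str = "p_diff_adj"):
        """Pairs whose adjusted p in the given family falls below ``alpha``."""
        if not hasattr(self, "records_"):
            raise RuntimeError("fit the estimator first")
        return [
            r.pair for r in self.records_
            if getattr(r, family) is not None and getattr(r, family) < alpha
        ]
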