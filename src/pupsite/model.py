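"""Model/Results interface over the full prediction pipeline.

:class:`PupylationSiteModel` holds an encoded window dataset (the design
matrix of 646 features plus binary labels); :meth:`PupylationSiteModel.fit`
runs feature ranking (mRMR by default), the incremental-feature-selection
sweep under jackknife nearest-neighbour evaluation, and finally the
grid-searched RBF-SVM on the optimal prefix. The returned
:class:`PupylationSiteResults` carries the ranked list, the IFS curve, the
optimum, both classifiers' jackknife metrics and the fitted SVM, with
``summary()``, ``predict()``, ``attribution()`` and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import attribution as attribution_mod
from . import ifs_eval, mrmr, svm_model
from .encoding import descriptor_checksum, descriptor_table, encode_dataset
from .feature_providers import load_annotations
from .ifs_eval import IFSCurve, MetricSet
from .mrmr import RankedList
from .sequence_io import (
    DEFAULT_FLANK,
    attach_sites,
    extract_all_windows,
    read_fasta,
    read_sites,
    sample_negatives,
)
from .svm_model import TrainedModel


class PupylationSiteModel:
    """Pupylation-site predictor built from an encoded window dataset.

    Parameters
    ----------
    X : (n_windows, n_features) array
        Feature matrix in descriptor-table column order.
    y : (n_windows,) array of {0, 1}
        Window labels (1 = annotated pupylation site).
    flank : int
        Window flank; fixes the descriptor table (646 features at flank 10).
    window_refs : optional list of (protein_id, center)
        Provenance of each row, used for grouped jackknife and reporting.
    """

    def __init__(self, X, y, flank: int = DEFAULT_FLANK, window_refs=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on sample count")
        self.flank = flank
        self.descriptors = descriptor_table(flank)
        if self.X.shape[1] != len(self.descriptors):
            raise ValueError(
                f"X has {self.X.shape[1]} columns; flank {flank} implies "
                f"{len(self.descriptors)}"
            )
        self.window_refs = window_refs

    @classmethod
    def from_windows(cls, windows, annotations_by_protein, flank: int | None = None):
        """Build from labelled peptide windows plus per-protein annotations."""
        X, y = encode_dataset(windows, annotations_by_protein)
        flank = windows[0].flank if (flank is None and windows) else (flank or DEFAULT_FLANK)
        refs = [(w.protein_id, w.center) for w in windows]
        return cls(X, y, flank=flank, window_refs=refs)

    @classmethod
    def from_files(
        cls,
        fasta_path,
        sites_path,
        annot_dir=None,
        fallback: bool = True,
        flank: int = DEFAULT_FLANK,
        neg_ratio: int | None = 3,
        seed: int = 0,
    ):
        """Build from a FASTA file, a site TSV and an annotation directory.

        Missing annotation files fall back to the deterministic substitution
        stand-in when ``fallback`` is true. ``neg_ratio=None`` keeps every
        negative window.
        """
        records = attach_sites(read_fasta(fasta_path), read_sites(sites_path))
        windows = extract_all_windows(records, flank=flank)
        if neg_ratio is not None:
            windows = sample_negatives(windows, ratio=neg_ratio, seed=seed)
        ann = {
            r.id: load_annotations(annot_dir, r.id, r.sequence, fallback=fallback)
            if annot_dir is not None
            else load_annotations(".", r.id, r.sequence, fallback=True)
            for r in records
        }
        return cls.from_windows(windows, ann, flank=flank)

    @classmethod
    def from_synthetic(cls, dataset, neg_ratio: int | None = 3, seed: int = 0):
        """Build from a :class:`~pupsite.synthetic_data.SyntheticDataset`."""
        from .synthetic_data import dataset_windows

        windows = dataset_windows(dataset)
        if neg_ratio is not None:
            windows = sample_negatives(windows, ratio=neg_ratio, seed=seed)
        return cls.from_windows(windows, dataset.annotations, flank=dataset.flank)

    def fit(
        self,
        ranking: str = "mrmr",
        mrmr_form: str = "MID",
        max_features: int | None = None,
        svm: bool = True,
        svm_jackknife: bool = True,
        C_grid=None,
        gamma_grid=None,
        folds: int = 5,
        seed: int = 0,
        standardize: bool = False,
    ) -> "PupylationSiteResults":
        """Run ranking → IFS → optimum → (optionally) grid-searched SVM.

        ``max_features`` truncates both the ranking and the IFS sweep (the
        full 646-step sweep is the default). ``svm_jackknife`` additionally
        evaluates the chosen (C, γ) by leave-one-out for honest SVM metrics
        and an AUC from its decision scores.
        """
        disc = mrmr.discretize(self.X)
        if ranking == "mrmr":
            ranked = mrmr.mrmr_rank(disc, self.y, n_select=max_features, form=mrmr_form)
        elif ranking == "maxrel":
            ranked = mrmr.maxrel_rank(disc, self.y)
            if max_features is not None:
                ranked = RankedList(
                    ranked.order[:max_features], ranked.scores[:max_features], ranked.criterion
                )
        else:
            raise ValueError(f"unknown ranking {ranking!r}")
        curve = ifs_eval.run_ifs(self.X, self.y, ranked)
        k_opt, nna_metrics = ifs_eval.find_optimum(curve)
        selected = ranked.top(k_opt)
        nna_auc = ifs_eval.roc_auc(
            ifs_eval.nna_margin_scores(self.X[:, ranked.positions(k_opt)], self.y), self.y
        )
        nna_metrics = MetricSet(
            sn=nna_metrics.sn, sp=nna_metrics.sp, ac=nna_metrics.ac,
            mcc=nna_metrics.mcc, auc=nna_auc,
        )
        trained = svm_metrics = svm_scores = None
        if svm:
            X_sel = self.X[:, ranked.positions(k_opt)]
            trained = svm_model.grid_search_train(
                X_sel,
                self.y,
                C_grid=C_grid,
                gamma_grid=gamma_grid,
                folds=folds,
                seed=seed,
                selected_feature_indices=selected,
                descriptor_checksum=descriptor_checksum(self.descriptors),
                standardize=standardize,
            )
            if svm_jackknife:
                pred, svm_scores = svm_model.jackknife_svm(X_sel, self.y, trained.C, trained.gamma)
                counts = ifs_eval.confusion(self.y, pred)
                svm_metrics = ifs_eval.metrics(counts, auc=ifs_eval.roc_auc(svm_scores, self.y))
        return PupylationSiteResults(
            model=self,
            ranked=ranked,
            curve=curve,
            k_optimal=k_opt,
            nna_metrics=nna_metrics,
            svm=trained,
            svm_metrics=svm_metrics,
            svm_jackknife_scores=svm_scores,
            seed=seed,
        )


@dataclass
class PupylationSiteResults:
    """Fit results: ranked features, IFS curve, optimum, and classifiers."""

    model: PupylationSiteModel
    ranked: RankedList
    curve: IFSCurve
    k_optimal: int
    nna_metrics: MetricSet
    svm: TrainedModel | None
    svm_metrics: MetricSet | None
    svm_jackknife_scores: np.ndarray | None
    seed: int

    @property
    def selected_features(self) -> np.ndarray:
        """1-based indices of the optimal feature set."""
        return self.ranked.top(self.k_optimal)

    def predict(self, X_full) -> tuple[np.ndarray, np.ndarray]:
        """Labels and decision scores for new windows (full 646-column matrix)."""
        if self.svm is None:
            raise ValueError("fit was run with svm=False; no classifier to apply")
        X_full = np.asarray(X_full, dtype=float)
        return svm_model.predict(self.svm, X_full[:, self.ranked.positions(self.k_optimal)])

    def attribution(self, grouping: str = "family", family_filter: str | None = None):
        """Attribution table of the optimal feature set."""
        return attribution_mod.tabulate(
            self.selected_features, self.model.descriptors, grouping, family_filter
        )

    def top_features(self, k: int = 10) -> pd.DataFrame:
        return attribution_mod.top_features_report(self.ranked, k, self.model.descriptors)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        n_pos = int(self.model.y.sum())
        n_neg = int(self.model.y.size - n_pos)
        fam = self.attribution("family").counts

        def fmt(m: MetricSet | None) -> str:
            if m is None:
                return "      (not evaluated)"
            parts = [
                f"Sn={m.sn:.3f}" if m.sn is not None else "Sn=NA",
                f"Sp={m.sp:.3f}" if m.sp is not None else "Sp=NA",
                f"Ac={m.ac:.3f}",
                f"MCC={m.mcc:.3f}",
            ]
            if m.auc is not None:
                parts.append(f"AUC={m.auc:.3f}")
            return "  ".join(parts)

        lines = [
            "Pupylation-site prediction results",
            "=" * 66,
            f"windows: {self.model.y.size} ({n_pos} positive, {n_neg} negative)"
            f"   features: {self.model.X.shape[1]}   ranking: {self.ranked.criterion}",
            f"optimal feature set: k* = {self.k_optimal}"
            f"   (families: " + ", ".join(f"{k}={v}" for k, v in fam.items() if v) + ")",
            "-" * 66,
            f"NNA jackknife @ k*:  {fmt(self.nna_metrics)}",
        ]
        if self.svm is not None:
            lines.append(
                f"SVM (RBF): C=2^{int(np.log2(self.svm.C))}, "
                f"gamma=2^{int(np.log2(self.svm.gamma))}, "
                f"{self.svm.n_grid_evaluations} grid pairs, seed={self.seed}"
            )
            lines.append(f"SVM jackknife @ k*:  {fmt(self.svm_metrics)}")
        lines.append("=" * 66)
        return "\n".join(lines)

    def plot_ifs(self, ax=None):
        """IFS curve: jackknife MCC against prefix size, optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        mccs = [m.mcc for m in self.curve.metric_sets]
        ax.plot(self.curve.ks, mccs, lw=1)
        ax.axvline(self.k_optimal, color="crimson", ls="--", lw=1)
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("jackknife MCC")
        ax.set_title(f"IFS curve (k* = {self.k_optimal})")
        return ax

    def plot_roc(self, ax=None):
        """ROC curve of the SVM's jackknife decision scores."""
        import matplotlib.pyplot as plt

        if self.svm_jackknife_scores is None:
            raise ValueError("no jackknife SVM scores; fit with svm_jackknife=True")
        pts = ifs_eval.roc_points(self.svm_jackknife_scores, self.model.y)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(pts["FPR"], pts["TPR"], lw=1.2)
        ax.plot([0, 1], [0, 1], color="grey", ls=":", lw=1)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"SVM ROC (AUC = {self.svm_metrics.auc:.3f})")
        return ax
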