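"""End-to-end orchestration of the two-block fusion experiment.

``run_experiment`` executes the full scheme from one configuration: load or
simulate the paired blocks, exclude interference regions, build the single
per-class Kennard-Stone split, rank the six pretreatments per block and
apply the winner, fit the tuned single-block PLS-DA and random-forest
models, run the variable-selection routes, build the three fusion levels,
and emit calibration/validation report tables plus a reproducibility
manifest.

One global seed fans out to named per-stage substreams
(``numpy.random.SeedSequence``) so changing one stage's stochasticity does
not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra_core import Modality, RunConfig, SpectralBlock, read_block
from .synthetic_data import simulate_blocks
from .preprocess import apply_pretreatment, exclude_regions, rank_pretreatments
from .split import CAL, VAL, split_by_class
from .models import fit_plsda, fit_rf, plsda_scores, quality_metrics, tune_rf
from .select import boruta_select, pca_extract, rfe_select, vip_select
from .fuse import high_level_fuse, low_level_fuse, mid_level_fuse
from .metrics_report import build_report

_pkg_version = "0.1.0"

_STAGE_NAMES = ("simulate", "rf_a", "rf_b", "select_a", "select_b",
                "rf_fused", "cv", "extra")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {name: int(ss.generate_state(1)[0] % (2**31 - 1))
            for name, ss in zip(_STAGE_NAMES, children)}


@dataclass
class RunManifest:
    """Provenance record: config, seeds, stage log, output hashes, warnings."""

    config: dict
    seeds: dict[str, int]
    version: str = _pkg_version
    stages: list[dict] = field(default_factory=list)
    output_hashes: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def log(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "version": self.version,
                    "stages": self.stages,
                    "output_hashes": self.output_hashes,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
                default=str,
            )


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


class StageError(RuntimeError):
    """An experiment stage failed; carries the stage name and completed log."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _singleton_sets(labels: np.ndarray) -> list[set]:
    return [{int(v)} for v in labels]


def run_experiment(
    config: RunConfig,
    data: str | tuple[str, str] = "simulate",
    blocks: tuple[SpectralBlock, SpectralBlock] | None = None,
    out_dir: str | Path | None = None,
    sim_kwargs: dict | None = None,
    selections: tuple[str, ...] = ("pcs", "rfe", "boruta"),
    rfe_kwargs: dict | None = None,
    boruta_kwargs: dict | None = None,
) -> tuple[RunManifest, dict[str, pd.DataFrame]]:
    """Run the full two-block fusion experiment.

    ``data`` is either ``"simulate"`` (paired blocks generated at the
    configured seed; ``sim_kwargs`` tunes sizes) or a pair of CSV paths
    (FT-MIR, NIR); pre-built ``blocks`` override both.  Returns the manifest
    and ``{"calibration": DataFrame, "validation": DataFrame}`` report
    tables with one row per dataset x model.
    """
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(config=config.to_dict(), seeds=seeds)
    stage = "load"
    try:
        if blocks is not None:
            block_a, block_b = blocks
        elif data == "simulate":
            stage = "simulate"
            block_a, block_b = simulate_blocks(seed=seeds["simulate"], **(sim_kwargs or {}))
        else:
            path_a, path_b = data
            block_a = read_block(path_a, Modality.FTMIR)
            block_b = read_block(path_b, Modality.NIR)
        manifest.log("load", ftmir_vars=block_a.n_variables, nir_vars=block_b.n_variables,
                     n_samples=block_a.n_samples)

        stage = "exclude_regions"
        for mod, blk_name in ((block_a.modality.value, "a"), (block_b.modality.value, "b")):
            regs = config.excluded_regions.get(mod, [])
            if regs:
                if blk_name == "a":
                    block_a = exclude_regions(block_a, regs)
                else:
                    block_b = exclude_regions(block_b, regs)
        manifest.log("exclude_regions", ftmir_vars=block_a.n_variables,
                     nir_vars=block_b.n_variables)

        # single split, reused by every model; distances on the raw
        # (region-excluded) concatenated blocks to avoid the circular
        # dependence of pretreatment ranking on the split
        stage = "split"
        split = split_by_class((block_a, block_b), ratio=config.split_ratio)
        manifest.log("split", n_calibration=split.n_calibration,
                     n_validation=split.n_validation,
                     per_class=dict(split.per_class_counts))

        stage = "pretreatment"
        best: dict[str, str] = {}
        for key, blk in (("FTMIR", block_a), ("NIR", block_b)):
            want = config.pretreatment.get(key, "auto")
            if want == "auto":
                reports, winner = rank_pretreatments(
                    blk, split, window=config.sg_window, poly=config.sg_poly)
                best[key] = winner
                manifest.log("rank_pretreatments", modality=key, best=winner,
                             candidates={r.method: round(r.accuracy, 4) for r in reports})
            else:
                best[key] = want
        block_a = apply_pretreatment(block_a, best["FTMIR"],
                                     window=config.sg_window, poly=config.sg_poly)
        block_b = apply_pretreatment(block_b, best["NIR"],
                                     window=config.sg_window, poly=config.sg_poly)
        manifest.log("pretreat", ftmir=best["FTMIR"], nir=best["NIR"])

        ids = block_a.sample_ids
        cal = split.indices(ids, CAL)
        val = split.indices(ids, VAL)
        y = block_a.labels
        classes = np.unique(y)
        results: dict[str, dict[str, tuple]] = {}
        scores_for_high: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

        def run_models(tag: str, Xmat: np.ndarray, rf_seed: int, keep_scores=False):
            X_cal, X_val = Xmat[cal], Xmat[val]
            out_scores = {}
            # PLS-DA
            m = fit_plsda(X_cal, y[cal], A="auto", seed=seeds["cv"])
            q = quality_metrics(m, X_cal, y[cal], X_val, y[val], seed=seeds["cv"])
            sc_cal, sc_val = plsda_scores(m, X_cal), plsda_scores(m, X_val)
            results[f"{tag} / PLS-DA"] = {
                "calibration": (y[cal], _singleton_sets(m.classes[np.argmax(sc_cal, 1)])),
                "validation": (y[val], _singleton_sets(m.classes[np.argmax(sc_val, 1)])),
            }
            manifest.log("plsda", dataset=tag, A=m.A, rmsep=round(q.rmsep, 4),
                         r2=round(q.r2, 4), q2=round(q.q2, 4))
            out_scores["plsda"] = (sc_cal, sc_val)
            # RF (tuned)
            cfg = tune_rf(X_cal, y[cal], seed=rf_seed, n_tree0=config.n_tree0)
            forest = fit_rf(X_cal, y[cal], n_tree=cfg.n_tree, m_try=cfg.m_try, seed=rf_seed)
            rf_cal, rf_val = forest.predict_scores(X_cal), forest.predict_scores(X_val)
            results[f"{tag} / RF"] = {
                "calibration": (y[cal], _singleton_sets(forest.classes_[np.argmax(rf_cal, 1)])),
                "validation": (y[val], _singleton_sets(forest.classes_[np.argmax(rf_val, 1)])),
            }
            manifest.log("rf", dataset=tag, n_tree=cfg.n_tree, m_try=cfg.m_try,
                         oob=round(cfg.oob_error, 4))
            out_scores["rf"] = (rf_cal, rf_val)
            if keep_scores:
                scores_for_high[tag] = out_scores
            return out_scores

        stage = "single_block"
        run_models("FT-MIR", block_a.X, seeds["rf_a"])
        run_models("NIR", block_b.X, seeds["rf_b"])

        stage = "low_level"
        low_X, _prov = low_level_fuse(block_a, block_b)
        run_models("Low-level", low_X, seeds["rf_fused"])
        manifest.log("low_level", fused_vars=low_X.shape[1])

        stage = "low_level_vip"
        m_low = fit_plsda(low_X[cal], y[cal], A="auto", seed=seeds["cv"])
        sel_vip = vip_select(m_low)
        if sel_vip.n_kept >= 2:
            run_models("Low-level (VIP)", low_X[:, sel_vip.indices], seeds["rf_fused"])
            manifest.log("vip_select", kept=sel_vip.n_kept)
        else:
            manifest.warnings.append("VIP selection kept < 2 variables; route skipped")

        def select_block(method: str, blk: SpectralBlock, rows: np.ndarray, seed_key: str):
            Xs, ys = blk.X[rows], blk.labels[rows]
            if method == "pcs":
                return pca_extract(Xs)
            if method == "rfe":
                kw = dict(n_tree0=min(config.n_tree0, 500), tune=False, n_tree=300,
                          folds=10, seed=seeds[seed_key])
                kw.update(rfe_kwargs or {})
                return rfe_select(Xs, ys, **kw)
            if method == "boruta":
                kw = dict(n_tree=300, seed=seeds[seed_key])
                kw.update(boruta_kwargs or {})
                return boruta_select(Xs, ys, **kw)
            raise ValueError(f"unknown selection {method!r}")

        all_rows = np.arange(len(ids))
        for method in selections:
            # mid-level: selection on the full sample set (study protocol;
            # leaks validation information into the selection)
            stage = f"mid_level_{method}"
            sa = select_block(method, block_a, all_rows, "select_a")
            sb = select_block(method, block_b, all_rows, "select_b")
            sa.leakage_warning = sb.leakage_warning = True
            manifest.warnings.append(
                f"mid-level ({method}): selection used all samples; "
                "validation information leaks into the selection")
            mid_X = mid_level_fuse(sa, block_a, sb, block_b)
            run_models(f"Mid-level ({method.upper() if method != 'pcs' else 'PCs'})",
                       mid_X, seeds["rf_fused"])
            manifest.log("mid_level", method=method,
                         kept_a=sa.n_kept, kept_b=sb.n_kept, fused_vars=mid_X.shape[1])

            # high-level: selection on calibration rows only, then per-block
            # models and decision voting
            stage = f"high_level_{method}"
            ha = select_block(method, block_a, cal, "select_a")
            hb = select_block(method, block_b, cal, "select_b")
            tag_a, tag_b = f"hi-{method}-a", f"hi-{method}-b"
            Fa, Fb = ha.transform(block_a.X), hb.transform(block_b.X)
            s_a = run_models(tag_a, Fa, seeds["rf_a"], keep_scores=True)
            s_b = run_models(tag_b, Fb, seeds["rf_b"], keep_scores=True)
            # per-block rows are intermediate; drop them from the report
            for t in (tag_a, tag_b):
                for fam in ("PLS-DA", "RF"):
                    results.pop(f"{t} / {fam}", None)
            label = method.upper() if method != "pcs" else "PCs"
            for fam in ("plsda", "rf"):
                fam_label = "PLS-DA" if fam == "plsda" else "RF"
                dec_cal = high_level_fuse(s_a[fam][0], s_b[fam][0], eps=config.tie_eps,
                                          classes=classes, true_labels=y[cal])
                dec_val = high_level_fuse(s_a[fam][1], s_b[fam][1], eps=config.tie_eps,
                                          classes=classes, true_labels=y[val])
                results[f"High-level ({label}) / {fam_label}"] = {
                    "calibration": (y[cal], [set(d.final) for d in dec_cal]),
                    "validation": (y[val], [set(d.final) for d in dec_val]),
                }
            manifest.log("high_level", method=method, kept_a=ha.n_kept, kept_b=hb.n_kept)

        stage = "report"
        meta = {"seeds": seeds, "config": config.to_dict(), "warnings": list(manifest.warnings)}
        tables = build_report(results, classes=[int(c) for c in classes], meta=meta)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            for tag, df in tables.items():
                p = out_dir / f"report_{tag}.csv"
                df.to_csv(p)
                manifest.output_hashes[p.name] = _hash_df(df)
            manifest.to_json(out_dir / "run_manifest.json")
        else:
            for tag, df in tables.items():
                manifest.output_hashes[f"report_{tag}.csv"] = _hash_df(df)
        return manifest, tables
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, manifest, exc) from exc
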