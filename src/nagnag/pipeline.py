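"""End-to-end orchestration: scan -> evidence -> features -> model -> predictions.

``run_pipeline`` chains the stages on real input files, writes every
intermediate table, and records a manifest (parameters, seed, per-stage
row counts, output checksums) sufficient to reproduce the run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (cross_validate, fit_naive_bayes, predict_proba)
from .evidence import (FilterParams, TrainingCriteria, count_support_bulk,
                       filter_alignments, select_training_set, summarize_labels)
from .features import (acceptor_window, extract_features, train_acceptor_pwm)
from .io import (read_alignment_tsv, read_bed12, write_contexts_fasta,
                 write_evidence_tsv, write_sites_tsv)
from .scan import Genome, extract_contexts, extract_introns, scan_nagnag_sites

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (missing inputs, clobbered outputs)."""


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    alignments: list  # [(path, pool, format)] with format in {bed12, tsv}
    out_dir: str
    filters: FilterParams = field(default_factory=FilterParams)
    criteria: TrainingCriteria = field(default_factory=TrainingCriteria)
    folds: int = 10
    seed: int = 0
    smoothing: float = 1.0
    reduced: bool = False
    overwrite: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    cfg = config
    for p in [cfg.genome, cfg.annotation] + [a[0] for a in cfg.alignments]:
        if not Path(p).exists():
            raise ConfigError(f"input path does not exist: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [f for f in ("sites.tsv", "predictions.tsv") if (out / f).exists()]
    if existing and not cfg.overwrite:
        raise ConfigError(f"outputs exist in {out} (use overwrite): {existing}")

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "filters": dataclasses.asdict(cfg.filters),
            "criteria": dataclasses.asdict(cfg.criteria),
            "folds": cfg.folds,
            "smoothing": cfg.smoothing,
            "reduced": cfg.reduced,
        },
        "stages": {},
    }

    stage = "scan"
    try:
        genome = Genome(cfg.genome)
        introns = extract_introns(cfg.annotation, genome)
        sites = scan_nagnag_sites(introns, genome)
        contexts = extract_contexts(sites, genome)
        write_sites_tsv(sites, out / "sites.tsv")
        write_contexts_fasta(contexts, out / "contexts.fasta")
        manifest["stages"][stage] = {"introns": len(introns), "sites": len(sites)}

        stage = "evidence"
        alignments = []
        for path, pool, fmt in cfg.alignments:
            reader = read_bed12 if fmt == "bed12" else read_alignment_tsv
            alignments.extend(reader(path, pool=pool))
        kept = filter_alignments(alignments, cfg.filters)
        counts = count_support_bulk(sites, kept, cfg.filters)
        labels = {l.site_id: l for l in select_training_set(counts.values(), cfg.criteria)}
        write_evidence_tsv(counts, labels, out / "evidence.tsv")
        report = summarize_labels(labels.values(), sites)
        (out / "summary.txt").write_text(report.to_text() + "\n")
        manifest["stages"][stage] = {
            "alignments": len(alignments), "alignments_kept": len(kept),
            "covered": report.n_covered, "E": report.n_E, "I": report.n_I,
            "EI": report.n_EI, "training": report.n_training,
        }

        stage = "features"
        background = genome.base_frequencies()
        windows = []
        for site in sites:
            lab = labels[site.site_id]
            if lab.training_class in ("E", "I"):
                which = "proximal" if lab.training_class == "E" else "distal"
                w = acceptor_window(contexts[site.site_id], which)
                if "X" not in w:
                    windows.append(w)
        if not windows:
            raise ValueError("no constitutive training sites to fit the acceptor model")
        pwm = train_acceptor_pwm(windows, background)
        pwm.to_json(out / "acceptor_pwm.json")
        frame, excluded = extract_features(sites, contexts, pwm)
        frame.to_csv(out / "features.tsv", sep="\t")
        manifest["stages"][stage] = {"features": frame.shape[1],
                                     "rows": len(frame), "excluded": len(excluded)}

        stage = "train"
        y = pd.Series({s: labels[s].training_class for s in frame.index})
        train_mask = y != "none"
        X_train, y_train = frame[train_mask], y[train_mask]
        model = fit_naive_bayes(X_train, y_train, alpha=cfg.smoothing)
        model.to_json(out / "model.json")
        folds = cfg.folds
        smallest = y_train.value_counts().min()
        if smallest < folds:
            log.warning("smallest class has %d members; reducing folds to %d",
                        smallest, smallest)
            folds = max(2, int(smallest))
        cv = cross_validate(X_train, y_train, folds=folds, seed=cfg.seed,
                            alpha=cfg.smoothing, reduced=cfg.reduced)
        pd.Series(cv.auc).rename("auc").to_csv(out / "cv_report.tsv", sep="\t")
        manifest["stages"][stage] = {"training_rows": len(X_train),
                                     "cv_scheme": cv.scheme,
                                     "auc": {k: round(v, 4) for k, v in cv.auc.items()}}

        stage = "predict"
        proba = predict_proba(model, frame)
        proba["predicted"] = proba[["p_E", "p_I", "p_EI"]].idxmax(axis=1).str[2:]
        proba["observed"] = [labels[s].observed for s in proba.index]
        proba.to_csv(out / "predictions.tsv", sep="\t")
        manifest["stages"][stage] = {"predictions": len(proba)}
    except ConfigError:
        raise
    except Exception as exc:  # annotate the failing stage, keep partials marked
        for f in out.glob("*.tsv"):
            f.rename(f.with_suffix(f.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {
        f.name: _sha256(f) for f in sorted(out.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
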