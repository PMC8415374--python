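"""End-to-end orchestration: simulate/load inputs, run every analysis stage,
and emit the per-stage "hourglass report" plus a reproducibility manifest.

The pipeline composes the library modules in the order of the analysis:
distal filtering against TSSs, stage-specificity calling, orthologous
translation and conserved-enhancer calling (both definitions), temporal
pleiotropy, per-stage gapped k-mer training on matched negatives, the
deltaSVM selection test, positive proportions split by conservation, and
the substitution/polymorphism excess test.  All randomness fans out from
one root seed via named substreams, and every output table declares the
thresholds used in a header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from ._rng import substream_seed
from .conservation import (
    call_conserved,
    call_stage_specific,
    classify_distal,
    compare_stage_proportions,
    conservation_summary,
    stage_specific_enhancers,
    temporal_pleiotropy,
)
from .genomic_io import (
    AlignedTriple,
    BlockMap,
    read_aligned_triple,
    read_bed,
    read_block_map,
    read_fasta,
    read_snp_table,
)
from .gkm import GappedKmerClassifier, cross_validate, sample_matched_negatives
from .intervals import STAGES, GenomicInterval
from .mk import mk_summary
from .selection import (
    estimate_spectrum,
    infer_ancestor,
    positive_proportion_by_group,
    test_enhancers,
)
from .synthetic import SyntheticWorld, WorldConfig, make_two_species_world

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "validate_config"]


@dataclass
class RunConfig:
    """Single configuration for a full run.

    Exactly one of ``simulate`` (a :class:`WorldConfig`) or ``inputs``
    (paths to on-disk data) must be set.  Analysis thresholds default to
    the study's printed values: q < 0.05, at least two substitutions,
    distal means > 500 bp from a TSS, relaxed conservation means < 1 kb.
    """

    seed: int = 0
    simulate: Optional[WorldConfig] = None
    inputs: Optional[dict] = None
    n_permutations: int = 1000
    base_sampling: str = "uniform"
    ts_tv_ratio: float = 3.0
    tail: str = "upper"
    q_threshold: float = 0.05
    min_substitutions: int = 2
    tss_distance: int = 500
    conservation_max_distance: int = 1000
    exclude_dinucleotides: bool = False
    gkm_l: int = 10
    gkm_k: int = 6
    gkm_C: float = 1.0
    cross_fit: bool = True
    gc_tol: float = 0.02
    repeat_tol: float = 0.1
    do_cross_validation: bool = False
    cv_folds: int = 5

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        analysis = raw.pop("analysis", {})
        cfg = cls(
            seed=int(raw.pop("seed", 0)),
            inputs=raw.pop("inputs", None),
            **analysis,
        )
        if raw:
            raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = WorldConfig(**sim)
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_REQUIRED_INPUTS = ("genome_a", "peaks_a", "peaks_b", "tss_a", "block_map",
                    "triples_dir", "snp_table")


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty means the config is runnable."""
    problems: list[str] = []
    if (config.simulate is None) == (config.inputs is None):
        problems.append("exactly one of 'simulate' or 'inputs' must be given")
    for name in ("n_permutations", "q_threshold", "min_substitutions",
                 "tss_distance", "conservation_max_distance"):
        if getattr(config, name) <= 0:
            problems.append(f"{name} must be positive")
    if config.tail not in ("upper", "lower", "two_sided"):
        problems.append(f"unknown tail {config.tail!r}")
    if config.base_sampling not in ("uniform", "ts_tv_weighted", "spectrum"):
        problems.append(f"unknown base_sampling {config.base_sampling!r}")
    if config.simulate is not None:
        try:
            config.simulate.validate()
        except ValueError as exc:
            problems.append(str(exc))
    if config.inputs is not None:
        for key in _REQUIRED_INPUTS:
            if key not in config.inputs:
                problems.append(f"inputs missing {key!r}")
        for key in ("peaks_a", "peaks_b"):
            stage_map = config.inputs.get(key)
            if isinstance(stage_map, Mapping):
                for st in stage_map:
                    if st not in STAGES:
                        problems.append(f"{key}: unknown stage label {st!r}")
                for st in STAGES:
                    if st not in stage_map:
                        problems.append(f"{key}: missing stage {st}")
        for key, val in (config.inputs or {}).items():
            paths = val.values() if isinstance(val, Mapping) else [val]
            for p in paths:
                if not Path(p).exists():
                    problems.append(f"inputs.{key}: path {p} does not exist")
    return problems


@dataclass
class PipelineData:
    """In-memory bundle of all inputs, whether simulated or loaded."""

    genome_a: dict[str, str]
    peaks_a: dict[str, list[GenomicInterval]]
    peaks_b: dict[str, list[GenomicInterval]]
    tss_a: list[GenomicInterval]
    tss_b: list[GenomicInterval]
    block_map: BlockMap
    triples: dict[str, AlignedTriple]
    snp_table: pd.DataFrame
    world: Optional[SyntheticWorld] = None


def _load_inputs(inputs: Mapping) -> PipelineData:
    genome_a = read_fasta(inputs["genome_a"])
    peaks_a = {st: read_bed(p, species="A", stage=st)
               for st, p in inputs["peaks_a"].items()}
    peaks_b = {st: read_bed(p, species="B", stage=st)
               for st, p in inputs["peaks_b"].items()}
    tss_a = read_bed(inputs["tss_a"], species="A")
    tss_b = read_bed(inputs["tss_b"], species="B") if "tss_b" in inputs else []
    block_map = read_block_map(inputs["block_map"])
    triples = {}
    for path in sorted(Path(inputs["triples_dir"]).glob("*.fa")):
        triple = read_aligned_triple(path)
        triples[triple.enhancer_id] = triple
    snp_table = read_snp_table(inputs["snp_table"])
    return PipelineData(genome_a, peaks_a, peaks_b, tss_a, tss_b,
                        block_map, triples, snp_table)


def _data_from_world(world: SyntheticWorld) -> PipelineData:
    return PipelineData(
        genome_a=world.genomes["speciesA"],
        peaks_a=world.peak_sets["speciesA"],
        peaks_b=world.peak_sets["speciesB"],
        tss_a=world.tss["speciesA"],
        tss_b=world.tss["speciesB"],
        block_map=world.block_map,
        triples=world.triples,
        snp_table=world.snp_table,
        world=world,
    )


def _write_tsv(path: Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    config: RunConfig,
    outdir: Union[str, Path],
    steps: Sequence[str] = ("conserve", "train", "selscan", "mk"),
) -> dict:
    """Run the pipeline end to end and write all outputs under ``outdir``.

    Returns a dict of the main result frames (conservation summaries,
    selection tables, MK tables, hourglass report, manifest).  ``steps``
    can truncate the run after an earlier stage (later stages depend on
    earlier ones and are skipped when omitted).
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}
    thresholds = (
        f"q_threshold={config.q_threshold} min_substitutions={config.min_substitutions} "
        f"tss_distance={config.tss_distance} "
        f"conservation_max_distance={config.conservation_max_distance} "
        f"tail={config.tail} base_sampling={config.base_sampling} "
        f"n_permutations={config.n_permutations} seed={config.seed}"
    )

    t0 = time.perf_counter()
    if config.simulate is not None:
        logger.info("step=simulate seed=%d", config.seed)
        world = make_two_species_world(config.simulate)
        world.write(outdir / "world")
        data = _data_from_world(world)
    else:
        logger.info("step=load")
        data = _load_inputs(config.inputs)
    timings["inputs"] = time.perf_counter() - t0

    # ------------------------------------------------------------------ conserve
    t0 = time.perf_counter()
    try:
        enhancers_a = {
            st: classify_distal(data.peaks_a[st], data.tss_a, config.tss_distance)
            for st in STAGES
        }
        enhancers_b = {
            st: classify_distal(data.peaks_b[st], data.tss_b, config.tss_distance)
            for st in STAGES
        }
    except KeyError as exc:
        raise RuntimeError(f"stage {exc} missing from peak sets") from exc
    calls_a = call_stage_specific(enhancers_a)
    calls_b = call_stage_specific(enhancers_b)
    specific_a = stage_specific_enhancers(calls_a)
    specific_b = stage_specific_enhancers(calls_b)
    cons_calls = call_conserved(
        specific_a, specific_b, data.block_map,
        max_distance=config.conservation_max_distance,
    )
    summaries = {
        mode: conservation_summary(specific_a, specific_b, cons_calls, mode)
        for mode in ("overlap", "within_1kb")
    }
    cons_table = pd.concat(summaries.values(), ignore_index=True)
    fisher_frames = []
    for mode, summ in summaries.items():
        counts = summ.rename(columns={"n_conserved": "k", "n_specific_A": "n"})
        fr = compare_stage_proportions(counts[["stage", "k", "n"]], reference="TP3")
        fr.insert(0, "mode", mode)
        fisher_frames.append(fr)
    cons_fisher = pd.concat(fisher_frames, ignore_index=True)
    usage, adjacent = temporal_pleiotropy(enhancers_a)
    _write_tsv(outdir / "conservation_summary.tsv", cons_table, thresholds)
    _write_tsv(outdir / "conservation_fisher.tsv", cons_fisher, thresholds)
    _write_tsv(outdir / "pleiotropy_usage.tsv", usage, thresholds)
    _write_tsv(outdir / "pleiotropy_adjacent.tsv", adjacent, thresholds)
    results.update(
        conservation=cons_table, conservation_fisher=cons_fisher,
        pleiotropy_usage=usage, pleiotropy_adjacent=adjacent,
        specific_a=specific_a, specific_b=specific_b, cons_calls=cons_calls,
    )
    timings["conserve"] = time.perf_counter() - t0
    logger.info("step=conserve done stages=%d", len(STAGES))
    if "train" not in steps:
        return _finish(config, outdir, results, timings)

    # ------------------------------------------------------------------ train
    # With cross_fit, each stage's enhancers are split into two folds and
    # every enhancer is later tested with the model trained on the other
    # fold (still the same stage's enhancers), which removes the
    # per-sequence memorization bias of scoring a training positive
    # against its own ancestor.
    t0 = time.perf_counter()
    models: dict[str, list[GappedKmerClassifier]] = {}
    fold_of: dict[str, int] = {}
    training: dict[str, object] = {}
    cv_rows = []
    for st in STAGES:
        enhancers = sorted(specific_a[st], key=lambda iv: iv.id)
        if len(enhancers) < (4 if config.cross_fit else 2):
            raise RuntimeError(f"stage {st}: too few stage-specific enhancers to train")
        folds = (
            [enhancers[0::2], enhancers[1::2]] if config.cross_fit else [enhancers]
        )
        stage_models = []
        stage_training = []
        for fi, fold in enumerate(folds):
            for iv in fold:
                fold_of[iv.id] = fi
            ts = sample_matched_negatives(
                fold, data.genome_a,
                gc_tol=config.gc_tol, repeat_tol=config.repeat_tol,
                seed=substream_seed(config.seed, f"negatives:{st}:{fi}"),
            )
            model = GappedKmerClassifier(
                l=config.gkm_l, k=config.gkm_k, C=config.gkm_C,
                random_state=substream_seed(config.seed, f"train:{st}:{fi}"),
            )
            model.fit(ts.positives + ts.negatives,
                      [1] * len(ts.positives) + [0] * len(ts.negatives))
            stage_models.append(model)
            stage_training.append(ts)
        models[st] = stage_models
        training[st] = stage_training
        if config.do_cross_validation:
            all_ts = sample_matched_negatives(
                enhancers, data.genome_a,
                gc_tol=config.gc_tol, repeat_tol=config.repeat_tol,
                seed=substream_seed(config.seed, f"negatives-cv:{st}"),
            )
            cv = cross_validate(
                all_ts.positives, all_ts.negatives,
                estimator=GappedKmerClassifier(
                    l=config.gkm_l, k=config.gkm_k, C=config.gkm_C),
                folds=config.cv_folds,
                seed=substream_seed(config.seed, f"cv:{st}"),
            )
            cv_rows.append({"stage": st, "cv_auc": cv["auc"]})
        logger.info("step=train stage=%s n_pos=%d folds=%d",
                    st, len(enhancers), len(folds))
    if cv_rows:
        cv_table = pd.DataFrame(cv_rows)
        _write_tsv(outdir / "cross_validation.tsv", cv_table, thresholds)
        results["cross_validation"] = cv_table
    results["models"] = models
    results["training"] = training
    timings["train"] = time.perf_counter() - t0
    if "selscan" not in steps:
        return _finish(config, outdir, results, timings)

    # ------------------------------------------------------------------ selscan
    t0 = time.perf_counter()
    calls_by_stage = {
        st: [
            infer_ancestor(data.triples[iv.id])
            for iv in specific_a[st]
            if iv.id in data.triples
        ]
        for st in STAGES
    }
    spectrum = None
    all_calls = [c for calls in calls_by_stage.values() for c in calls]
    if all_calls:
        spectrum = estimate_spectrum(all_calls)
    sel_frames = []
    for st in STAGES:
        fold_frames = []
        n_dropped = 0
        for fi, model in enumerate(models[st]):
            # score fold fi's enhancers with the other fold's model
            scoring = (
                models[st][1 - fi] if config.cross_fit else models[st][0]
            )
            fold_calls = [
                c for c in calls_by_stage[st] if fold_of.get(c.enhancer_id, 0) == fi
            ]
            res = test_enhancers(
                scoring, fold_calls,
                n_permutations=config.n_permutations,
                base_sampling=config.base_sampling,
                spectrum=spectrum,
                min_substitutions=config.min_substitutions,
                tail=config.tail,
                q_threshold=config.q_threshold,
                exclude_dinucleotides=config.exclude_dinucleotides,
                seed=substream_seed(config.seed, f"selscan:{st}:{fi}"),
                ts_tv_ratio=config.ts_tv_ratio,
            )
            n_dropped += res.attrs["n_dropped"]
            fold_frames.append(res)
            if not config.cross_fit:
                break
        res = pd.concat(fold_frames, ignore_index=True)
        if len(res):
            # q-values over the stage's whole tested set, not per fold
            res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
            res["positive_call"] = res["q_value"] < config.q_threshold
        res.insert(1, "stage", st)
        sel_frames.append(res)
        logger.info(
            "step=selscan stage=%s tested=%d positive=%d dropped=%d",
            st, len(res), int(res["positive_call"].sum()), n_dropped,
        )
    selection_results = pd.concat(sel_frames, ignore_index=True)
    # conservation label per enhancer (strict overlap definition)
    cons_label = {
        c.enhancer_id: ("conserved" if c.conserved_overlap else "nonconserved")
        for st in STAGES
        for c in cons_calls[st]
    }
    selection_results["conservation"] = selection_results["enhancer_id"].map(cons_label)
    _write_tsv(outdir / "selection_results.tsv", selection_results, thresholds)
    # per-stage positive proportions, overall and split by conservation
    prop_rows = []
    for st, sub in selection_results.groupby("stage"):
        row = {
            "stage": st,
            "n_tested": len(sub),
            "n_positive": int(sub["positive_call"].sum()),
            "positive_proportion": float(sub["positive_call"].mean()),
        }
        for label in ("conserved", "nonconserved"):
            grp = sub[sub["conservation"] == label]
            row[f"n_{label}"] = len(grp)
            row[f"positive_proportion_{label}"] = (
                float(grp["positive_call"].mean()) if len(grp) else np.nan
            )
        prop_rows.append(row)
    positive_props = pd.DataFrame(prop_rows).sort_values("stage").reset_index(drop=True)
    prop_fisher = compare_stage_proportions(
        positive_props.rename(columns={"n_positive": "k", "n_tested": "n"})[
            ["stage", "k", "n"]
        ],
        reference="TP3",
    )
    _write_tsv(outdir / "positive_proportions.tsv", positive_props, thresholds)
    _write_tsv(outdir / "positive_proportions_fisher.tsv", prop_fisher, thresholds)
    results.update(
        selection=selection_results,
        positive_proportions=positive_props,
        positive_proportions_fisher=prop_fisher,
        spectrum=spectrum,
    )
    timings["selscan"] = time.perf_counter() - t0
    if "mk" not in steps:
        return _finish(config, outdir, results, timings)

    # ------------------------------------------------------------------ mk
    t0 = time.perf_counter()
    mk_frames = []
    for st, sub in selection_results.groupby("stage"):
        if sub["positive_call"].nunique() == 2:
            mk_frames.append(mk_summary(sub, data.snp_table, label=st))
    if selection_results["positive_call"].nunique() == 2:
        mk_frames.append(mk_summary(selection_results, data.snp_table, label="pooled"))
    mk_table = (
        pd.concat(mk_frames, ignore_index=True) if mk_frames else pd.DataFrame()
    )
    _write_tsv(outdir / "mk_test.tsv", mk_table, thresholds)
    results["mk"] = mk_table
    timings["mk"] = time.perf_counter() - t0

    # ------------------------------------------------------------------ report
    report_rows = []
    for st in STAGES:
        ov = summaries["overlap"].set_index("stage").loc[st]
        kb = summaries["within_1kb"].set_index("stage").loc[st]
        prow = positive_props.set_index("stage").loc[st]
        mk_p = mk_or = np.nan
        if len(mk_table) and st in set(mk_table.get("stage", [])):
            mk_row = mk_table.set_index("stage").loc[st]
            mk_p, mk_or = mk_row["fisher_p"], mk_row["odds_ratio"]
        report_rows.append(
            {
                "stage": st,
                "n_peaks": len(data.peaks_a[st]),
                "n_enhancers": len(enhancers_a[st]),
                "n_stage_specific": int(ov["n_specific_A"]),
                "n_with_ortholog": int(ov["n_with_ortholog"]),
                "conserved_proportion_overlap": ov["proportion_A"],
                "conserved_proportion_1kb": kb["proportion_A"],
                "jaccard": ov["jaccard"],
                "n_tested": int(prow["n_tested"]),
                "positive_proportion": prow["positive_proportion"],
                "positive_proportion_conserved": prow["positive_proportion_conserved"],
                "positive_proportion_nonconserved": prow[
                    "positive_proportion_nonconserved"
                ],
                "mk_odds_ratio": mk_or,
                "mk_fisher_p": mk_p,
            }
        )
    report = pd.DataFrame(report_rows)
    _write_tsv(outdir / "hourglass_report.tsv", report, thresholds)
    results["report"] = report
    return _finish(config, outdir, results, timings)


def _finish(config: RunConfig, outdir: Path, results: dict, timings: dict) -> dict:
    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    outputs = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg_dict,
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    results["outdir"] = outdir
    return results
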