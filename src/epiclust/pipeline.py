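"""End-to-end pipeline: simulate -> call -> clean -> cluster -> characterize.

The pipeline mirrors the study workflow.  A synthetic cohort is drawn; for
each subject, paired-end bisulfite reads are simulated from every amplicon
at that subject's true per-CpG methylation and the caller re-estimates the
percentages (sample x amplicon batches failing coverage/conversion QC are
excluded, i.e. set missing).  Subjects with more than half their data
missing are removed, remaining holes are hot-deck imputed, a constrained
Gaussian mixture is selected by BIC on the bivariate T-scores, and the
resulting clusters are characterized variable by variable.

Every output file is recorded in a manifest with a SHA-256 digest; reruns
with the same configuration are bit-identical.

Read-level simulation dominates run time; ``read_level=False`` feeds the
generator's methylation percentages directly into the statistics, which is
useful for fast cohort-scale runs when the caller itself is not under
study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import BisulfiteScoring
from .amplicons import study_references, write_references
from .calling import call_sample, profiles_to_frame
from .cohort import (
    CohortSpec,
    generate_cohort,
    inject_missingness,
    study_cohort_spec,
)
from .mixture import FAMILIES, map_assign, select_model
from .readsim import simulate_bisulfite_pairs
from .stats import StatsConfig, characterize, clean_and_impute

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    seed: int = 1
    n_subjects: int = 200
    missing_rate: float = 0.0
    # read-level simulation / calling
    read_level: bool = True
    n_pairs: int = 150
    read_len: int | None = None
    error_rate: float = 0.001
    conversion_eff: float = 0.995
    min_coverage: int = 100
    min_conversion: float = 99.0
    # clustering
    families: tuple[str, ...] = FAMILIES
    k_min: int = 1
    k_max: int = 4
    n_restarts: int = 10
    tol: float = 1e-8
    # statistics
    variant: str = "welch"
    alpha: float = 0.05
    bonferroni_family: str = "methylation"

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_pairs < 1:
            raise ValueError("n_subjects and n_pairs must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.min_coverage < 1 or not 0 <= self.min_conversion <= 100:
            raise ValueError("bad QC thresholds")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("bad K range")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unsupported families: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(d["families"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subject_meth_probs(row: pd.Series, ref) -> np.ndarray:
    """Per-CpG methylation probabilities for one subject and amplicon.

    Analyzed CpGs take the subject's cohort percentages; any unanalyzed
    CpGs (sites the assay carries but the study does not report) take the
    mean of the analyzed ones.
    """
    vals = np.array(
        [row[f"{ref.name}_CpG{i + 1}"] for i in range(len(ref.analyzed_cpgs))],
        float,
    )
    probs = np.full(ref.n_cpg, float(np.nanmean(vals)) / 100.0)
    for slot, cpg_index in enumerate(ref.analyzed_cpgs):
        probs[cpg_index] = vals[slot] / 100.0
    return np.clip(probs, 0.0, 1.0)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages and write tables, models, reports, and a manifest."""
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("config", str(exc)) from exc
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("references", "cohort", "missingness", "reads",
                     "imputation", "clustering")
    }
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    def _write_json(obj, name: str) -> Path:
        p = out / name
        p.write_text(json.dumps(obj, indent=1, default=str))
        written.append(p)
        return p

    # --- simulate ---
    try:
        refs = study_references(seed=stage_seeds["references"])
        write_references(refs, out / "references.fasta", out / "references.json")
        written += [out / "references.fasta", out / "references.json"]
        spec: CohortSpec = study_cohort_spec(n=config.n_subjects)
        cohort, truth = generate_cohort(spec, seed=stage_seeds["cohort"])
        if config.missing_rate > 0:
            cohort = inject_missingness(
                cohort, config.missing_rate, seed=stage_seeds["missingness"]
            )
        _write_df(cohort, "cohort.csv")
        _write_df(
            pd.DataFrame({"subject_id": cohort["subject_id"], "true_component": truth}),
            "truth_labels.csv",
        )
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- call ---
    exclusions: list[dict] = []
    if config.read_level:
        try:
            scoring = BisulfiteScoring()
            read_rng = np.random.default_rng(stage_seeds["reads"])
            call_frames = []
            analysis = cohort.copy()
            for _, row in cohort.iterrows():
                pairs = []
                for ref in refs:
                    probs = _subject_meth_probs(row, ref)
                    if np.isnan(probs).any():  # subject missing this amplicon
                        continue
                    ps = simulate_bisulfite_pairs(
                        ref,
                        probs,
                        conversion_eff=config.conversion_eff,
                        error_rate=config.error_rate,
                        n_pairs=config.n_pairs,
                        read_len=config.read_len,
                        seed=int(read_rng.integers(0, 2**31 - 1)),
                        name_prefix=f"{row.subject_id}:{ref.name}",
                    )
                    pairs.extend(ps.pairs)
                profiles, _rej = call_sample(
                    pairs, refs, scoring,
                    min_coverage=config.min_coverage,
                    min_conversion=config.min_conversion,
                )
                frame = profiles_to_frame(row.subject_id, profiles, refs)
                call_frames.append(frame)
                for ref in refs:
                    prof = profiles.get(ref.name)
                    cols = [
                        f"{ref.name}_CpG{i + 1}"
                        for i in range(len(ref.analyzed_cpgs))
                    ]
                    if prof is None or not prof.qc.passed:
                        analysis.loc[analysis.subject_id == row.subject_id, cols] = np.nan
                        exclusions.append(
                            {
                                "subject_id": row.subject_id,
                                "amplicon": ref.name,
                                "reasons": prof.qc.reasons if prof else ["no retained pairs"],
                            }
                        )
                    else:
                        called = [prof.meth_pct[i] for i in prof.analyzed_cpgs]
                        analysis.loc[analysis.subject_id == row.subject_id, cols] = called
            _write_df(pd.concat(call_frames, ignore_index=True), "methylation_calls.csv")
        except Exception as exc:
            raise PipelineError("call", str(exc)) from exc
    else:
        analysis = cohort
    _write_json({"excluded": exclusions}, "qc_exclusions.json")

    # --- clean / impute ---
    try:
        cleaned, removed = clean_and_impute(analysis, seed=stage_seeds["imputation"])
        _write_df(cleaned, "cohort_clean.csv")
        _write_df(removed, "removed_subjects.csv")
    except Exception as exc:
        raise PipelineError("clean", str(exc)) from exc

    # --- cluster ---
    try:
        X = cleaned[["internalizing", "externalizing"]].to_numpy(float)
        best, ranking = select_model(
            X,
            K_range=range(config.k_min, config.k_max + 1),
            families=config.families,
            seed=stage_seeds["clustering"],
            n_restarts=config.n_restarts,
            tol=config.tol,
        )
        _write_df(ranking, "model_ranking.csv")
        model_for_groups = best
        if best.K != 2:  # characterization is a two-group contrast
            two = ranking[ranking["K"] == 2]
            if len(two):
                from .mixture import fit_mixture

                fam = two.iloc[0]["family"]
                model_for_groups = fit_mixture(
                    X, 2, fam, seed=stage_seeds["clustering"],
                    n_restarts=config.n_restarts, tol=config.tol,
                )
        assign = map_assign(model_for_groups, X)
        _write_json(
            {
                "family": best.family, "K": best.K,
                "weights": best.weights.tolist(),
                "means": best.means.tolist(),
                "variances": best.variances.tolist(),
                "loglik": best.loglik, "m": best.m, "n": best.n, "bic": best.bic,
            },
            "best_model.json",
        )
        _write_df(
            pd.DataFrame(
                {
                    "subject_id": cleaned["subject_id"],
                    "cluster": assign.label_names(),
                    "responsibility": assign.responsibilities.max(axis=1),
                }
            ),
            "assignments.csv",
        )
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc

    # --- characterize ---
    try:
        report = characterize(
            cleaned,
            assign.label_names(),
            StatsConfig(
                variant=config.variant,
                alpha=config.alpha,
                bonferroni_family=config.bonferroni_family,
            ),
        )
        _write_df(report.table, "cluster_report.csv")
        _write_json(
            {
                "cluster_sizes": report.cluster_sizes,
                "errors": report.errors,
            },
            "cluster_report_meta.json",
        )
    except Exception as exc:
        raise PipelineError("characterize", str(exc)) from exc

    manifest = {
        "epiclust_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": stage_seeds,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
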