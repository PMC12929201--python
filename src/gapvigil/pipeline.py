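"""End-to-end pipeline orchestration with a reproducibility manifest.

A run executes the requested stages in dependency order — simulate,
annotate, landscape, the spontaneous-report screen and the claims screen —
on a single declarative configuration, writes every output as delimited
text, and records a manifest (inputs, seeds, outputs, SHA-256 checksums)
sufficient to reproduce the run bit-for-bit.  Heatmap matrices follow the
publication-figure layout: one drugs x study-types matrix per subpopulation,
rows ordered by descending overall publication frequency (ties
alphabetical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from .case_control import ScreenConfig, run_screen
from .disproportionality import screen_signals
from .landscape import (
    MIN_PRESCRIPTIONS,
    SUBPOP_TO_POPULATION,
    build_pregnancy_cohort,
    filter_min_prescriptions,
    gap_summary,
    pediatric_rates,
    pregnancy_postpartum_rates,
    rank_no_evidence,
)
from .lexicon import (
    STUDY_TYPES,
    annotate_corpus,
    build_drug_lexicon,
    count_publications,
    default_population_lexicon,
)
from .simulate import SimConfig, gen_abstract_corpus, gen_claims_cohort, \
    gen_report_database, study_years

logger = logging.getLogger("gapvigil")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "export_heatmap_matrix"]

ALL_STAGES = ("simulate", "annotate", "landscape", "faers_screen", "claims_screen")


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a pipeline run."""

    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    sim: SimConfig | None = None
    min_prescriptions: int = MIN_PRESCRIPTIONS
    p_threshold: float = 1e-5
    window_days: int = 60
    input_paths: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.min_prescriptions < 0 or self.p_threshold <= 0 or self.window_days < 1:
            raise ValueError("thresholds must be positive")
        for p in self.input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"declared input path missing: {p}")


@dataclass
class RunManifest:
    seed: int
    stages: tuple[str, ...]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    counts: dict[str, int] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    diagnostic: str | None = None

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed, "stages": list(self.stages),
            "outputs": dict(sorted(self.outputs.items())),
            "counts": dict(sorted(self.counts.items())),
            "completed": self.completed,
            "failed_stage": self.failed_stage, "diagnostic": self.diagnostic,
        }, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(manifest: RunManifest, path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    manifest.outputs[path.name] = _sha256(path)


def export_heatmap_matrix(
    publication_table: pd.DataFrame,
    rate_table: pd.DataFrame,
    plot_path: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Drugs x study-type publication matrices, one per subpopulation.

    Rows are the subpopulation's prescribed drugs ordered by descending
    overall publication frequency, ties broken alphabetically; missing cells
    are zero.  With ``plot_path``, also renders one heatmap panel per
    subpopulation into a single figure.
    """
    matrices: dict[str, pd.DataFrame] = {}
    for subpop, sub in rate_table.groupby("subpopulation"):
        drugs = sorted(sub["drug"].unique())
        tag = SUBPOP_TO_POPULATION.get(subpop, subpop)
        pub = publication_table[publication_table["population"] == tag]
        pivot = (
            pub.pivot_table(index="drug", columns="study_type",
                            values="paper_count", aggfunc="sum", fill_value=0)
            .reindex(index=drugs, columns=list(STUDY_TYPES), fill_value=0)
            .fillna(0).astype(int)
        )
        totals = pivot.sum(axis=1)
        ordered = sorted(pivot.index, key=lambda d: (-totals[d], d))
        matrices[subpop] = pivot.loc[ordered]
    if plot_path is not None and matrices:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(matrices),
                                 figsize=(3 * len(matrices), 6), squeeze=False)
        for ax, (subpop, m) in zip(axes[0], sorted(matrices.items())):
            ax.imshow(m.values, aspect="auto", cmap="viridis")
            ax.set_title(subpop)
            ax.set_xticks(range(len(m.columns)), m.columns)
            ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return matrices


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages and write the run manifest.

    Stage failures are recorded in the manifest (partial completion plus the
    failing stage's diagnostic) and re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim if config.sim is not None else SimConfig(seed=config.seed)
    manifest = RunManifest(seed=sim.seed, stages=config.stages)
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage in config.stages:
                logger.info("stage %s starting", stage)
                _STAGES[stage](config, sim, state, manifest, out)
                manifest.completed.append(stage)
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.diagnostic = f"{type(exc).__name__}: {exc}"
        _write(manifest, out / "manifest.json", manifest.to_json())
        raise
    _write(manifest, out / "manifest.json", manifest.to_json())
    # manifest checksum list excludes the manifest itself
    return manifest


def _stage_simulate(config, sim, state, manifest, out: Path) -> None:
    records, corpus_truth = gen_abstract_corpus(sim)
    reports, report_truth = gen_report_database(sim)
    cohort, claims_truth = gen_claims_cohort(sim)
    state.update(records=records, corpus_truth=corpus_truth, reports=reports,
                 report_truth=report_truth, cohort=cohort,
                 claims_truth=claims_truth)
    _write(manifest, out / "corpus.jsonl", gio.corpus_to_jsonl(records))
    _write(manifest, out / "labels.json", json.dumps(
        {rid: sorted(info["study_types"])
         for rid, info in corpus_truth.record_labels.items()},
        indent=0, sort_keys=True))
    _write(manifest, out / "reports.jsonl", gio.reports_to_jsonl(reports))
    for path in gio.write_cohort(cohort, out / "claims"):
        manifest.outputs[f"claims/{path.name}"] = _sha256(path)
    manifest.counts.update(n_papers=len(records), n_reports=len(reports),
                           n_persons=len(cohort.persons))


def _stage_annotate(config, sim, state, manifest, out: Path) -> None:
    # fall back to precomputed stage outputs under out_dir for partial runs
    if "records" in state:
        records = state["records"]
        labels = {rid: info["study_types"]
                  for rid, info in state["corpus_truth"].record_labels.items()}
    else:
        records = gio.corpus_from_jsonl((out / "corpus.jsonl").read_text())
        labels = {rid: frozenset(v) for rid, v in
                  json.loads((out / "labels.json").read_text()).items()}
    lex = build_drug_lexicon({d: [d] for d in sim.drug_names})
    annotations = annotate_corpus(records, lex, default_population_lexicon(),
                                  study_labels=labels)
    pubs = count_publications(annotations)
    state["publications"] = pubs
    _write(manifest, out / "publication_counts.tsv",
           pubs.to_csv(sep="\t", index=False))
    manifest.counts["n_annotated"] = len(annotations)


def _stage_landscape(config, sim, state, manifest, out: Path) -> None:
    cohort = state.get("cohort")
    if cohort is None:
        cohort = gio.read_cohort(out / "claims")
    pubs = state.get("publications")
    if pubs is None:
        pubs = pd.read_csv(out / "publication_counts.tsv", sep="\t")
    episodes = build_pregnancy_cohort(cohort, sim.delivery_codes)
    preg = pregnancy_postpartum_rates(episodes, cohort.prescriptions)
    ped, n_neg = pediatric_rates(cohort, study_years(sim))
    rates = pd.concat([preg, ped], ignore_index=True)
    rates = filter_min_prescriptions(rates, config.min_prescriptions)
    summary = gap_summary(rates, pubs)
    state["rates"] = rates
    state["gap"] = summary
    _write(manifest, out / "rate_table.tsv", rates.to_csv(sep="\t", index=False))
    _write(manifest, out / "gap_summary.tsv",
           summary.cells.to_csv(sep="\t", index=False))
    ranked_frames = []
    for subpop in sorted(rates["subpopulation"].unique()):
        for rank, drug in enumerate(rank_no_evidence(rates, pubs, subpop), 1):
            ranked_frames.append((subpop, rank, drug))
    _write(manifest, out / "no_evidence_ranking.tsv",
           pd.DataFrame(ranked_frames,
                        columns=["subpopulation", "rank", "drug"])
           .to_csv(sep="\t", index=False))
    matrices = export_heatmap_matrix(pubs, rates)
    for subpop, m in matrices.items():
        _write(manifest, out / f"heatmap_{subpop}.tsv", m.to_csv(sep="\t"))
    manifest.counts["n_eligible_episodes"] = sum(e.eligible for e in episodes)
    manifest.counts["n_negative_age_skipped"] = n_neg
    manifest.counts["n_rate_rows"] = len(rates)


def _stage_faers_screen(config, sim, state, manifest, out: Path) -> None:
    reports = state.get("reports")
    if reports is None:
        reports = gio.reports_from_jsonl((out / "reports.jsonl").read_text())
    decisions = screen_signals(reports)
    state["signal_decisions"] = decisions
    _write(manifest, out / "signal_decisions.tsv", gio.decisions_to_tsv(decisions))
    manifest.counts["n_signals"] = sum(d.is_signal for d in decisions)


def _stage_claims_screen(config, sim, state, manifest, out: Path) -> None:
    cohort = state.get("cohort")
    if cohort is None:
        cohort = gio.read_cohort(out / "claims")
    episodes = build_pregnancy_cohort(cohort, sim.delivery_codes)
    screen_cfg = ScreenConfig(window_days=config.window_days,
                              p_threshold=config.p_threshold, seed=sim.seed)
    results = run_screen(episodes, list(sim.drug_names), cohort.prescriptions,
                         cohort.diagnoses, screen_cfg, codes=sim.icd10_codes)
    state["screen_results"] = results
    _write(manifest, out / "claims_screen.tsv", gio.screen_results_to_tsv(results))
    manifest.counts["n_claims_flags"] = sum(r.passes_threshold for r in results)


_STAGES = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "landscape": _stage_landscape,
    "faers_screen": _stage_faers_screen,
    "claims_screen": _stage_claims_screen,
}
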