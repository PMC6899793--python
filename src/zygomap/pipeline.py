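"""End-to-end mapping workflow: mask -> site filters -> family segregation
-> zygosity inference -> pattern filter -> deduction -> reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as zio
from .core import GenotypeMatrix, Individual
from .filters import (
    FilterConfig,
    FilterLog,
    exclude_shared_high_af,
    group_allele_frequencies,
    mask_low_confidence,
    population_site_filter,
    select_family_segregating,
)
from .segregation import (
    InheritanceModel,
    MODELS,
    ProgenyRecord,
    classify_parent_zygosity,
    infer_inheritance,
)
from .zygosity import (
    CandidateSet,
    ZygosityPattern,
    apply_zygosity_filter,
    build_pattern,
    candidate_report,
    deduce_unknown_zygosity,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    family: str
    model: InheritanceModel
    pattern: ZygosityPattern
    candidates: CandidateSet
    deduced: dict[str, str]
    stage_counts: dict[str, int]
    filter_log: FilterLog
    report: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def run_pipeline(
    matrix: GenotypeMatrix,
    family: str,
    progeny: list[ProgenyRecord] | None = None,
    config: FilterConfig | None = None,
    model: InheritanceModel | None = None,
    alpha: float = 0.05,
    missing_policy: str = "lenient",
) -> PipelineResult:
    """Run the full zygosity-mapping cascade for one family.

    Without progeny records the pattern degrades to phenotype-forced sets
    only (a warning is recorded); the inheritance model must then be given.
    """
    config = config or FilterConfig()
    flog = FilterLog()
    warnings: list[str] = []
    counts: dict[str, int] = {"input": matrix.n_sites}

    masked = mask_low_confidence(matrix, config)
    retained = population_site_filter(masked, config, flog)
    counts["population_filter"] = retained.n_sites

    segregating = select_family_segregating(retained, family, config, flog)
    counts["family_segregating"] = segregating.n_sites

    freqs = group_allele_frequencies(segregating, family=family)
    segregating = exclude_shared_high_af(segregating, freqs, config, flog)
    counts["shared_af_excluded"] = segregating.n_sites

    # inheritance + per-parent zygosity
    fam_inds = [ind for ind in matrix.individuals if ind.family == family]
    calls = {}
    if progeny:
        fam_ids = {i.id for i in fam_inds}
        fam_records = [r for r in progeny if r.parent_id in fam_ids]
        phen = {i.id: i.phenotype for i in fam_inds}
        fam_records = [
            r if r.parent_phenotype in ("mutant", "wildtype")
            else type(r)(**{**r.__dict__, "parent_phenotype": phen.get(r.parent_id, "unknown")})
            for r in fam_records
        ]
        if model is None:
            inference = infer_inheritance(fam_records, alpha)
            model = inference.model
            for line in inference.evidence:
                log.info("inheritance: %s", line)
        calls = {
            r.parent_id: classify_parent_zygosity(r, model, alpha) for r in fam_records
        }
    else:
        warnings.append("no progeny records: pattern is phenotype-forced only")
        if model is None:
            raise ValueError("an inheritance model is required when no progeny data is given")

    pattern = build_pattern(fam_inds, model, calls)

    fam_matrix = segregating.take_individuals(
        [i for i, ind in enumerate(segregating.individuals) if ind.family == family]
    )
    candidates = apply_zygosity_filter(fam_matrix, pattern, missing_policy)
    counts["zygosity_pass"] = candidates.n_candidates

    new_pattern, deduced, deduce_warnings = deduce_unknown_zygosity(candidates, pattern)
    warnings.extend(deduce_warnings)
    if deduced:
        candidates = apply_zygosity_filter(fam_matrix, new_pattern, missing_policy)
        counts["zygosity_pass_after_deduction"] = candidates.n_candidates
        pattern = new_pattern

    report = candidate_report(candidates, family=family)
    return PipelineResult(
        family=family,
        model=model,
        pattern=pattern,
        candidates=candidates,
        deduced=deduced,
        stage_counts=counts,
        filter_log=flog,
        report=report,
        warnings=warnings,
    )


def allele_frequency_table(matrix: GenotypeMatrix, family: str | None = None) -> pd.DataFrame:
    """Per-site mutant-allele frequencies by phenotype group, genome-ordered;
    the underlying table of the per-chromosome frequency plot."""
    freqs = group_allele_frequencies(matrix, family=family)
    freqs = freqs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return freqs


def plot_allele_frequencies(table: pd.DataFrame, path: str | Path) -> bool:
    """Scatter mutant-group and wild-type-group frequencies along each
    chromosome.  Returns False (table-only) when matplotlib is unavailable
    or the table is empty."""
    if table.empty:
        return False
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        log.warning("matplotlib not installed; frequency plot skipped")
        return False
    chroms = list(dict.fromkeys(table["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = table[table["chrom"] == chrom]
        ax.scatter(sub["pos"] / 1e6, sub["f_mutant_group"], s=6, label="mutant group")
        ax.scatter(sub["pos"] / 1e6, sub["f_wildtype_group"], s=6, label="wild-type group")
        ax.set_ylim(-0.05, 1.05)
        ax.set_ylabel(f"chr {chrom}")
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True
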