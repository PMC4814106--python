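"""End-to-end analysis: matrix -> parsimony search -> consensus -> homoplasy
profile -> Bremer supports -> treeness statistics.

Every stage persists a plain-text intermediate in the output directory so
each number in the report can be recomputed independently; given a seed the
whole run is deterministic (no timestamps enter the artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .character_matrix import (
    CharacterMatrix,
    binarize,
    informative_mask,
    read_matrix,
    write_nexus,
)
from .parsimony import (
    ANCESTOR_NAME,
    NodeSupport,
    SearchConfig,
    add_zero_ancestor,
    bremer_supports,
    category_summary,
    ensemble_fit,
    heuristic_search,
    majority_consensus,
    profile_fits,
    root_at,
    strict_consensus,
)
from .treeness import mean_character_distance, treeness_report

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "render_report", "StageError"]

log = logging.getLogger("culturetree")


class StageError(RuntimeError):
    """A pipeline stage failed; ``exit_code`` follows the CLI convention
    (2 validation, 3 escalated search-cap warning, 4 I/O)."""

    def __init__(self, stage: str, message: str, exit_code: int = 2):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    matrix: str
    outdir: str = "culturetree_out"
    dialect: Optional[str] = None
    categories: Optional[str] = None
    seed: int = 0
    n_addition_sequences: int = 10
    swap: str = "TBR"
    max_saved_trees: int = 10_000
    steepest_descent: bool = False
    bremer_kmax: int = 3
    max_quartets: Optional[int] = None
    #: average per-character fits over this many most-parsimonious trees
    #: (1 = first tree only)
    profile_trees: int = 25
    fail_on_tree_cap: bool = False
    log_level: str = "INFO"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            n_addition_sequences=self.n_addition_sequences,
            swap=self.swap,
            seed=self.seed,
            max_saved_trees=self.max_saved_trees,
            steepest_descent=self.steepest_descent,
        )

    def config_hash(self) -> str:
        """Fingerprint of the analytic settings (where results are written
        and how chatty the log is do not affect the numbers)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        d.pop("log_level")
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    best_length: int
    n_mpts: int
    ensemble: dict  # mean ensemble CI/RI over MPTs, all + informative-only
    informative_count: int  # on the input matrix (without the ancestor)
    category_summary: dict
    bremer: list  # NodeSupport
    treeness: dict
    strict_newick: str
    majority_newick: str
    mpt_newicks: list
    provenance: dict
    warnings_: list = field(default_factory=list)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise StageError("setup", str(e), exit_code=4)

    try:
        matrix = read_matrix(config.matrix, dialect=config.dialect, categories=config.categories)
    except FileNotFoundError as e:
        raise StageError("read", str(e), exit_code=4)
    except ValueError as e:
        raise StageError("read", str(e), exit_code=2)
    log.info("stage=read taxa=%d characters=%d", matrix.n_taxa, matrix.n_characters)

    info_input = informative_mask(matrix)
    search_matrix = add_zero_ancestor(matrix)
    write_nexus_safe(search_matrix, outdir / "search_matrix.nex")

    t0 = time.perf_counter()
    result = heuristic_search(
        search_matrix, config.search_config(), retain_slack=config.bremer_kmax
    )
    log.info(
        "stage=search elapsed=%.2fs best_length=%d n_mpts=%d",
        time.perf_counter() - t0,
        result.best_length,
        len(result.trees),
    )
    warnings_ = list(result.warnings_)
    if result.warnings_ and config.fail_on_tree_cap:
        raise StageError("search", "; ".join(result.warnings_), exit_code=3)
    (outdir / "search.log").write_text(
        "".join(f"replicate={r}\tbest_length={ln}\n" for r, ln in result.log)
    )

    rooted = [root_at(t, ANCESTOR_NAME, prune=True) for t in result.trees]
    strict = strict_consensus(rooted)
    majority = majority_consensus(rooted)
    (outdir / "mpts.nwk").write_text(
        "".join(t.newick(lengths=False) + "\n" for t in rooted)
    )
    strict_nwk = strict.newick(lengths=False)
    majority_nwk = majority.newick(lengths=False, support=True)
    (outdir / "strict_consensus.nwk").write_text(strict_nwk + "\n")
    (outdir / "majority_consensus.nwk").write_text(majority_nwk + "\n")

    profile_set = result.trees[: max(1, config.profile_trees)]
    fits = profile_fits(profile_set, search_matrix)
    info_search = informative_mask(search_matrix)
    scores = [ensemble_fit(t, search_matrix) for t in profile_set]
    ensemble = {
        "ci": _mean(s.ci for s in scores),
        "ri": _mean(s.ri for s in scores),
        "ci_informative": _mean(s.ci_informative for s in scores),
        "ri_informative": _mean(s.ri_informative for s in scores),
    }
    cats = category_summary(fits, search_matrix.characters, info_search)
    with open(outdir / "character_fits.tsv", "w") as fh:
        fh.write("char\tname\tcategory\tinformative\tm\ts\tg\tci\tri\n")
        for f, cdef, keep in zip(fits, search_matrix.characters, info_search):
            ri = "" if f.ri is None else f"{f.ri:.4f}"
            fh.write(
                f"{f.index}\t{cdef.name}\t{cdef.category}\t{int(keep)}\t"
                f"{f.m}\t{f.s:.2f}\t{f.g}\t{f.ci:.4f}\t{ri}\n"
            )

    t0 = time.perf_counter()
    bremer = bremer_supports(
        search_matrix,
        majority,
        config.search_config(),
        kmax=config.bremer_kmax,
        root_taxon=ANCESTOR_NAME,
        exhaustive=search_matrix.n_taxa <= 8,
        result=result,
    )
    log.info("stage=bremer elapsed=%.2fs nodes=%d", time.perf_counter() - t0, len(bremer))
    with open(outdir / "bremer.tsv", "w") as fh:
        fh.write("clade\tbremer\tlower_bound\n")
        for ns in bremer:
            fh.write(
                f"{','.join(sorted(ns.clade))}\t{ns.bremer}\t{int(ns.lower_bound)}\n"
            )

    t0 = time.perf_counter()
    binary = binarize(matrix)
    D = mean_character_distance(binary)
    tr = treeness_report(D, max_quartets=config.max_quartets, seed=config.seed)
    log.info("stage=treeness elapsed=%.2fs quartets=%d", time.perf_counter() - t0, tr.n_quartets)
    treeness = {
        "mean_delta": tr.mean_delta,
        "mean_q_residual": tr.mean_q_residual,
        "n_quartets": tr.n_quartets,
        "per_taxon_delta": tr.per_taxon_delta,
    }
    (outdir / "treeness.json").write_text(json.dumps(treeness, indent=2, sort_keys=True))

    report = AnalysisReport(
        best_length=result.best_length,
        n_mpts=len(result.trees),
        ensemble=ensemble,
        informative_count=sum(info_input),
        category_summary=cats,
        bremer=bremer,
        treeness=treeness,
        strict_newick=strict_nwk,
        majority_newick=majority_nwk,
        mpt_newicks=[t.newick(lengths=False) for t in rooted],
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        },
        warnings_=warnings_,
    )
    render_report(report, "json", outdir / "report.json")
    render_report(report, "text", outdir / "report.txt")
    return report


def write_nexus_safe(matrix: CharacterMatrix, path) -> None:
    """NEXUS needs single-character symbols; fall back to CSV otherwise."""
    from .character_matrix import write_csv

    try:
        write_nexus(matrix, path)
    except ValueError:
        write_csv(matrix, Path(path).with_suffix(".csv"))


def _mean(it) -> float:
    vals = list(it)
    return sum(vals) / len(vals)


def _report_dict(report: AnalysisReport) -> dict:
    d = dataclasses.asdict(report)
    d["bremer"] = [
        {"clade": sorted(ns.clade), "bremer": ns.bremer, "lower_bound": ns.lower_bound}
        for ns in report.bremer
    ]
    return d


def render_report(report: AnalysisReport, fmt: str, path=None):
    """Render as ``json`` (schema-stable), ``text`` (summary block plus
    binned CI/RI tables mirroring the published figures), or ``tsv``."""
    if fmt == "json":
        text = json.dumps(_report_dict(report), indent=2, sort_keys=True)
    elif fmt == "tsv":
        lines = ["key\tvalue"]
        lines.append(f"best_length\t{report.best_length}")
        lines.append(f"n_mpts\t{report.n_mpts}")
        for k, v in sorted(report.ensemble.items()):
            lines.append(f"ensemble_{k}\t{v:.4f}")
        lines.append(f"informative_count\t{report.informative_count}")
        lines.append(f"mean_delta\t{report.treeness['mean_delta']:.4f}")
        lines.append(f"mean_q_residual\t{report.treeness['mean_q_residual']:.4f}")
        text = "\n".join(lines) + "\n"
    elif fmt == "text":
        out = []
        out.append("culturetree analysis report")
        out.append("===========================")
        out.append(f"tree length          : {report.best_length}")
        out.append(f"most-parsimonious trees kept : {report.n_mpts}")
        out.append(
            "ensemble CI / RI     : "
            f"{report.ensemble['ci']:.3f} / {report.ensemble['ri']:.3f}"
        )
        out.append(
            "  informative only   : "
            f"{report.ensemble['ci_informative']:.3f} / {report.ensemble['ri_informative']:.3f}"
        )
        out.append(f"informative characters : {report.informative_count}")
        out.append(
            "treeness             : "
            f"delta = {report.treeness['mean_delta']:.3f}, "
            f"Q-residual = {report.treeness['mean_q_residual']:.4f} "
            f"({report.treeness['n_quartets']} quartets)"
        )
        out.append("")
        out.append("CI distribution by category (informative characters, bins of 0.1)")
        bins = " ".join(f"{lo / 10:.1f}" for lo in range(10))
        out.append(f"{'category':<22} n    mean_ci  {bins}")
        for cat, s in report.category_summary["by_category"].items():
            if s["n_informative"] == 0:
                continue
            hist = " ".join(f"{c:3d}" for c in s["ci_hist"])
            out.append(
                f"{cat:<22} {s['n_informative']:<4d} {s['mean_ci']:.3f}    {hist}"
            )
        out.append("")
        out.append("Bremer supports (clade size, decay):")
        for ns in report.bremer:
            tag = ">=" if ns.lower_bound else "="
            out.append(f"  |{len(ns.clade):3d}| {tag} {ns.bremer}")
        out.append("")
        if report.warnings_:
            out.append("warnings: " + "; ".join(report.warnings_))
        text = "\n".join(out) + "\n"
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
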