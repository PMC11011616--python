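"""End-to-end orchestration: load -> patch -> configure -> pairwise
agreement -> delimitation -> (optional) parsimony search -> consensus ->
Bremer -> audit -> elongation indices, with a manifest recording inputs.

Every stage writes a machine-readable report into the output directory;
a failing stage aborts the run with the stage name while retaining the
outputs already written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .agreement import pairwise_table, table_to_tsv
from .audit import (
    VertebraMeasurement,
    aei,
    audit,
    load_bundled_diagnostics,
    load_bundled_specimens,
    suggest_referral,
)
from .io import read_nexus, read_patches, read_settings, read_tnt
from .model import AnalysisSettings, CharacterMatrix, apply_patches, configure
from .parsimony import (
    MAX_EXHAUSTIVE_TAXA,
    bremer_support,
    exhaustive_search,
    heuristic_search,
    tree_length,
)
from .trees import strict_consensus

logger = logging.getLogger("morphotax")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(Exception):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    matrix_path: str
    out_dir: str
    patches_path: str | None = None
    settings_path: str | None = None
    settings: AnalysisSettings | None = None
    focal_otus: list[str] = field(default_factory=list)
    run_search: bool = False
    search_n_starts: int = 3
    run_bremer: bool = False
    bremer_max_extra: int = 3
    run_audit: bool = True
    measurements: list[VertebraMeasurement] = field(default_factory=list)
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_matrix(path: Path) -> CharacterMatrix:
    text = path.read_text()
    if "#NEXUS" in text.upper():
        return read_nexus(text)
    return read_tnt(text)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "inputs": {},
        "stages": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    # ---- load ----
    stage("load")
    try:
        matrix_path = Path(config.matrix_path)
        matrix = _load_matrix(matrix_path)
        manifest["inputs"]["matrix"] = {
            "path": str(matrix_path),
            "sha256": _sha256(matrix_path),
        }
    except Exception as e:
        raise PipelineError("load", e)

    # ---- patch ----
    if config.patches_path:
        stage("patch")
        try:
            ppath = Path(config.patches_path)
            patches = read_patches(ppath.read_text())
            matrix, log = apply_patches(matrix, patches, strict=True)
            (out / "patch_log.txt").write_text("\n".join(log) + "\n")
            manifest["inputs"]["patches"] = {
                "path": str(ppath),
                "sha256": _sha256(ppath),
            }
        except Exception as e:
            raise PipelineError("patch", e)

    # ---- configure ----
    settings = config.settings
    if config.settings_path:
        stage("configure")
        try:
            spath = Path(config.settings_path)
            settings = read_settings(spath.read_text())
            manifest["inputs"]["settings"] = {
                "path": str(spath),
                "sha256": _sha256(spath),
            }
        except Exception as e:
            raise PipelineError("configure", e)
    if settings is not None:
        stage("configure" if not config.settings_path else "configure-apply")
        try:
            matrix = configure(matrix, settings)
        except Exception as e:
            raise PipelineError("configure", e)
    else:
        settings = AnalysisSettings()

    if (config.run_search or config.run_bremer) and settings.seed is None:
        raise PipelineError(
            "validate", ValueError("search stages require an explicit seed")
        )

    # ---- pairwise agreement / delimitation ----
    if config.focal_otus:
        stage("compare")
        try:
            rows = pairwise_table(matrix, config.focal_otus)
            (out / "pairwise.tsv").write_text(table_to_tsv(rows))
            (out / "pairwise.json").write_text(json.dumps(rows, indent=2))
        except Exception as e:
            raise PipelineError("compare", e)

    # ---- search / consensus / bremer ----
    if config.run_search:
        stage("search")
        try:
            n_active = sum(matrix.active_otus)
            criterion = (
                "length" if settings.weighting == "equal" else "iw"
            )
            if n_active <= MAX_EXHAUSTIVE_TAXA:
                result = exhaustive_search(
                    matrix, criterion, k=settings.k,
                    extended=settings.weighting == "extended_implied",
                )
            else:
                result = heuristic_search(
                    matrix,
                    criterion,
                    n_starts=config.search_n_starts,
                    seed=settings.seed,
                    k=settings.k,
                    extended=settings.weighting == "extended_implied",
                )
            best = result.best_trees[0]
            score = tree_length(matrix, best, k=settings.k)
            search_report = {
                "criterion": result.criterion,
                "best_score": result.best_score,
                "n_best_trees": len(result.best_trees),
                "length": score.length,
                "ci": score.ci,
                "ri": score.ri,
                "iw_score": score.iw_score,
                "log": result.log,
            }
            (out / "search.json").write_text(json.dumps(search_report, indent=2))
            (out / "best_trees.nwk").write_text(
                "\n".join(t.to_newick() for t in result.best_trees) + "\n"
            )
        except Exception as e:
            raise PipelineError("search", e)

        stage("consensus")
        try:
            cons = strict_consensus(result.best_trees)
            (out / "consensus.nwk").write_text(cons.to_newick() + "\n")
        except Exception as e:
            raise PipelineError("consensus", e)

        if config.run_bremer:
            stage("bremer")
            try:
                decay = bremer_support(
                    matrix,
                    best_trees=result.best_trees,
                    max_extra_steps=config.bremer_max_extra,
                    seed=settings.seed,
                )
                report = [
                    {
                        "clade": sorted(clade),
                        "bremer": v,
                    }
                    for clade, v in sorted(
                        decay.items(), key=lambda kv: sorted(kv[0])
                    )
                ]
                (out / "bremer.json").write_text(json.dumps(report, indent=2))
            except Exception as e:
                raise PipelineError("bremer", e)

    # ---- audit ----
    if config.run_audit:
        stage("audit")
        try:
            diagnostics = load_bundled_diagnostics()
            specimens = load_bundled_specimens()
            result_audit = audit(specimens, diagnostics)
            referrals = {
                sp.id: suggest_referral(sp, diagnostics) for sp in specimens
            }
            (out / "audit.json").write_text(
                json.dumps(
                    {"audit": result_audit, "referrals": referrals}, indent=2
                )
            )
        except Exception as e:
            raise PipelineError("audit", e)

    # ---- elongation indices ----
    if config.measurements:
        stage("aei")
        try:
            rows = [aei(m) for m in config.measurements]
            (out / "aei.json").write_text(json.dumps(rows, indent=2))
        except Exception as e:
            raise PipelineError("aei", e)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
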