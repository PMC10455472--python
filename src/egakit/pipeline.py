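"""Stability-driven refinement workflow.

Per group: run EGA, bootstrap it, compute item stability against the
empirical solution, remove every item whose own-dimension stability falls
below the threshold (all at once by default, or worst-first iteratively),
then re-estimate EGA and the bootstrap on the reduced matrix.  Multi-group
runs repeat this independently per group with derived seeds and emit a
combined report (markdown table plus a full JSON payload).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .bootstrap import BootEGA, BootEGAResults
from .communities import DEFAULT_STEPS
from .corr import LabeledCorrelationMatrix
from .exceptions import PipelineError
from .glasso import EstimationSettings
from .stability import CONSISTENCY_THRESHOLD, ITEM_STABILITY_THRESHOLD

_STAGE_SEED_STRIDE = 100_003  # prime stride separating stage/group streams


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the full EGA -> bootEGA -> refine workflow."""

    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    n_boot: int = 500
    seed: int = 0
    confidence: float = 0.95
    item_stability_threshold: float = ITEM_STABILITY_THRESHOLD
    consistency_threshold: float = CONSISTENCY_THRESHOLD
    removal_mode: str = "single_pass"
    steps: int = DEFAULT_STEPS

    def __post_init__(self) -> None:
        if not 0 < self.item_stability_threshold < 1:
            raise ValueError("item_stability_threshold must be in (0, 1)")
        if not 0 < self.consistency_threshold < 1:
            raise ValueError("consistency_threshold must be in (0, 1)")
        if self.removal_mode not in ("single_pass", "iterative"):
            raise ValueError("removal_mode must be 'single_pass' or 'iterative'")


@dataclass(frozen=True)
class GroupResult:
    """Initial and final (post-removal) analyses for one group."""

    label: str
    initial: BootEGAResults
    removed: tuple[str, ...]
    final: BootEGAResults

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "removed": list(self.removed),
            "initial": self.initial.to_dict(),
            "final": self.final.to_dict(),
        }

    def cluster_text(self, which: str = "final") -> str:
        res = {"initial": self.initial, "final": self.final}[which]
        sol = res.solution
        parts = [f"{len(s)} items: " + ", ".join(sorted(s)) for s in sol.item_sets()]
        return f"{sol.n_dims} clusters (" + " | ".join(parts) + ")"


def _run_stage(
    corr: LabeledCorrelationMatrix, config: PipelineConfig, seed: int
) -> BootEGAResults:
    model = BootEGA(corr, config.estimation, config.steps)
    return model.fit(n_boot=config.n_boot, seed=seed, confidence=config.confidence)


def analyze_group(
    corr: LabeledCorrelationMatrix,
    config: PipelineConfig | None = None,
    label: str = "group",
) -> GroupResult:
    """The per-group workflow: bootEGA, flag, remove, re-estimate.

    Items are flagged against their own dimension in the *initial*
    empirical EGA solution.  ``single_pass`` removes all flagged items at
    once; ``iterative`` removes the single worst item and repeats until
    none remain below threshold.  If nothing is flagged the final stage is
    the initial one.  Removal is refused if fewer than three items would
    remain.
    """
    config = config or PipelineConfig()
    initial = _run_stage(corr, config, config.seed)
    removed: list[str] = []
    stage = 1

    def flagged(res: BootEGAResults) -> list[str]:
        own = res.stability.own_stability
        bad = [l for l in res.solution.labels if own[l] < config.item_stability_threshold]
        return sorted(bad, key=lambda l: own[l])  # worst first

    current = initial
    current_corr = corr
    while True:
        bad = flagged(current)
        if not bad:
            break
        drop = bad if config.removal_mode == "single_pass" else bad[:1]
        keep = [l for l in current_corr.labels if l not in set(drop)]
        if len(keep) < 3:
            raise PipelineError(
                f"removing {drop} would leave {len(keep)} items (< 3); "
                f"refusing to refine group {label!r}"
            )
        removed.extend(drop)
        current_corr = current_corr.subset(keep)
        current = _run_stage(current_corr, config, config.seed + stage * _STAGE_SEED_STRIDE)
        stage += 1
        if config.removal_mode == "single_pass":
            break
    return GroupResult(label=label, initial=initial, removed=tuple(removed), final=current)


def analyze_groups(
    inputs: list[tuple[str, LabeledCorrelationMatrix]],
    config: PipelineConfig | None = None,
) -> tuple[list[GroupResult | None], dict]:
    """Independent per-group runs with derived seeds plus a combined report.

    Group i runs with seed ``(seed + i * stride) mod 2^31``.  A failing
    group is recorded in the report and does not stop the others.
    """
    if not inputs:
        raise ValueError("need at least one (label, corr) input")
    config = config or PipelineConfig()
    results: list[GroupResult | None] = []
    entries = []
    for i, (label, corr) in enumerate(inputs):
        gseed = (config.seed + i * 13 * _STAGE_SEED_STRIDE) % 2**31
        gconfig = replace(config, seed=gseed)
        try:
            res = analyze_group(corr, gconfig, label=label)
            results.append(res)
            entries.append({"status": "ok", "seed": gseed, **res.to_dict()})
        except Exception as exc:  # noqa: BLE001 - report and continue
            results.append(None)
            entries.append({"status": "failed", "seed": gseed, "label": label,
                            "error": str(exc)})
    report = {
        "config": {
            "gamma": config.estimation.gamma,
            "n_lambda": config.estimation.n_lambda,
            "lambda_min_ratio": config.estimation.lambda_min_ratio,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "confidence": config.confidence,
            "item_stability_threshold": config.item_stability_threshold,
            "consistency_threshold": config.consistency_threshold,
            "removal_mode": config.removal_mode,
            "walktrap_steps": config.steps,
        },
        "groups": entries,
    }
    return results, report


def report_json(report: dict) -> str:
    """Deterministic serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2)


def report_markdown(results: list[GroupResult | None], report: dict) -> str:
    """Combined table: per group, the EGA clusters, the bootEGA typical
    clusters, and the final clusters after removing unstable items."""
    lines = [
        "| Group | EGA | bootEGA (typical) | Final (unstable items removed) |",
        "| --- | --- | --- | --- |",
    ]
    for res, entry in zip(results, report["groups"]):
        if res is None:
            lines.append(f"| {entry['label']} | failed: {entry['error']} | | |")
            continue
        init_sol = res.initial.solution
        typ_sol = res.initial.typical[1]
        fin_sol = res.final.solution

        def fmt(sol):
            return f"{sol.n_dims} clusters: " + " / ".join(
                "(" + ", ".join(sorted(s)) + ")" for s in sol.item_sets()
            )

        removed = ", ".join(res.removed) if res.removed else "none removed"
        lines.append(
            f"| {res.label} | {fmt(init_sol)} | {fmt(typ_sol)} | "
            f"{fmt(fin_sol)} [{removed}] |"
        )
    return "\n".join(lines) + "\n"
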