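"""End-to-end orchestration: simulate -> run-algo -> build-rehr ->
validate -> estimate, with a reproducibility manifest.

A run is driven by one config mapping (usually loaded from YAML).  Every
source of randomness derives from the single top-level seed; rerunning
the same config yields byte-identical outputs and manifest.  All stage
outputs are plain delimited/JSON files so any stage can also be run
standalone through the CLI.

A config may instead carry a ``confusion`` block (raw 2x2 counts, e.g.
a published table) in which case only the estimation stage runs — the
"replay" mode used to reproduce printed results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import io as cio
from .algorithms import shipped_config, load_config, run_algorithm
from .rehr import build_rehr_batch, render_rehr, scan_for_leaks
from .simulate import (
    MSCohortParams,
    PCaCohortParams,
    simulate_ms_cohort,
    simulate_pca_cohort,
    write_truth,
)
from .stats import (
    ConfusionTable,
    StratumWeight,
    estimate_performance,
    report,
    weighted_npv,
)
from .study import (
    ReviewerProfile,
    SamplingPlan,
    sample_validation_set,
    score_against_algorithm,
    simulate_adjudication,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _estimate_payload(est) -> dict:
    return {
        "table": dataclasses.asdict(est.table),
        "ppv": est.ppv,
        "npv": est.npv,
        "ci_ppv": est.ci_ppv,
        "ci_npv": est.ci_npv,
        "alpha": est.alpha,
        "weighted": est.weighted,
        "reported": {
            "ppv_pct": est.reported_ppv_pct,
            "npv_pct": est.reported_npv_pct,
            "ci_ppv_pct": est.reported_ci_ppv_pct,
            "ci_npv_pct": est.reported_ci_npv_pct,
        },
    }


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest (also written).

    Stage seeds are fixed offsets of the top-level ``seed`` so the
    manifest alone reproduces the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    manifest: dict[str, Any] = {"seed": seed, "alpha": alpha, "stages": {}, "outputs": {}}

    if "confusion" in config:
        # replay mode: estimate straight from provided counts
        c = config["confusion"]
        table = ConfusionTable(tp=c["tp"], fp=c["fp"], tn=c["tn"], fn=c["fn"])
        est = estimate_performance(table, alpha=alpha, weighted=bool(c.get("weighted", False)))
        (out / "report.txt").write_text(report(est, case_label=config.get("case_label", "Case")))
        payload = _estimate_payload(est)
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest["stages"]["estimate"] = payload["reported"]
        manifest["outputs"] = {p.name: _sha256(p) for p in sorted(out.glob("report.*"))}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest

    mode = config.get("mode", "ms")
    try:
        records, truths = _stage_simulate(config, mode, seed, out, manifest)
        flags, strata_labels = _stage_algorithm(config, mode, records, out, manifest)
        est = _stage_validate(
            config, records, truths, flags, strata_labels, seed, alpha, out, manifest
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"pipeline failed: {exc}") from exc

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(config, mode, seed, out, manifest):
    sim_cfg = dict(config.get("simulate", {}))
    sim_cfg.setdefault("seed", seed)
    if mode == "ms":
        fu = sim_cfg.get("followup_years")
        if isinstance(fu, list):
            sim_cfg["followup_years"] = tuple(fu)
        params = MSCohortParams(**sim_cfg)
        records, truths = simulate_ms_cohort(params)
    elif mode == "mcrpc":
        params = PCaCohortParams(**sim_cfg)
        records, truths = simulate_pca_cohort(params)
    else:
        raise PipelineError(f"simulate: unknown mode {mode!r}")
    cio.write_events(records, out / "events.csv", out / "patients.csv")
    write_truth(truths, out / "truth.csv")
    manifest["stages"]["simulate"] = {
        "mode": mode,
        "n_patients": len(records),
        "n_events": sum(len(r.events) for r in records),
        "params": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in dataclasses.asdict(params).items()},
    }
    return records, truths


def _stage_algorithm(config, mode, records, out, manifest):
    algo_path = config.get("algorithm_config")
    algo = load_config(algo_path) if algo_path else shipped_config(
        "ms_relapse" if mode == "ms" else "mcrpc"
    )
    calls, flags = run_algorithm(records, algo, mode)
    strata_labels = {
        c.patient_id: c.label for c in calls if mode == "mcrpc"
    } or None
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "episode_start": c.episode_start.isoformat(),
                "label": c.label,
            }
            for c in calls
        ]
    ).to_csv(out / "calls.csv", index=False)
    pd.DataFrame(
        [{"patient_id": pid, "algo_case": int(f)} for pid, f in flags.items()]
    ).to_csv(out / "flags.csv", index=False)
    manifest["stages"]["algorithm"] = {
        "n_calls": len(calls),
        "n_cases": sum(flags.values()),
        "n_noncases": len(flags) - sum(flags.values()),
    }
    return flags, strata_labels


def _stage_validate(config, records, truths, flags, strata_labels, seed, alpha, out, manifest):
    samp_cfg = dict(config.get("sampling", {}))
    strata_spec = samp_cfg.pop("strata", None)
    plan = SamplingPlan(
        n_cases=int(samp_cfg.get("n_cases", 100)),
        n_noncases=int(samp_cfg.get("n_noncases", 100)),
        noncase_strata=tuple((s, int(n)) for s, n in strata_spec) if strata_spec else None,
        seed=seed + 1,
    )
    sample_ids = sample_validation_set(flags, plan, strata=strata_labels)

    by_pid = {r.patient_id: r for r in records}
    salt = str(config.get("salt", f"salt-{seed}"))
    rehrs, ledger = build_rehr_batch([by_pid[p] for p in sample_ids], id_salt=salt)
    docs_dir = out / "rehrs"
    docs_dir.mkdir(exist_ok=True)
    leaks = []
    all_ids = [r.patient_id for r in records]
    locations = sorted({r.location for r in records if r.location})
    for rehr in rehrs:
        doc = render_rehr(rehr)
        leaks.extend(scan_for_leaks(doc, patient_ids=all_ids, locations=locations))
        (docs_dir / f"{rehr.review_id}.txt").write_text(doc)
    if leaks:
        raise PipelineError(f"build-rehr: anonymization leak(s): {leaks[:5]}")

    truth_by_pid = {t.patient_id: t.is_case for t in truths}
    truth_by_rid = {rid: truth_by_pid[pid] for rid, pid in ledger.items()}
    reviewers = tuple(
        ReviewerProfile(**rv) for rv in config.get("reviewers", [{}, {}])
    )
    adjudications = simulate_adjudication(
        list(truth_by_rid),
        truth_by_rid,
        reviewers=reviewers,
        consensus_rule=config.get("consensus_rule", "truth"),
        seed=seed + 2,
    )
    pd.DataFrame(
        [
            {
                "review_id": a.review_id,
                "verdict": a.verdict,
                "reviewer_1": int(a.reviewer_verdicts[0]),
                "reviewer_2": int(a.reviewer_verdicts[1]),
                "consensus_used": int(a.consensus_used),
            }
            for a in adjudications
        ]
    ).to_csv(out / "adjudication.csv", index=False)
    flags_by_rid = {rid: flags[pid] for rid, pid in ledger.items()}
    json.dump(
        {rid: {"patient_id": pid, "algo_case": bool(flags_by_rid[rid])} for rid, pid in ledger.items()},
        (out / "unblinded_ledger.json").open("w"),
        indent=2,
        sort_keys=True,
    )

    table = score_against_algorithm(adjudications, flags_by_rid)
    est = estimate_performance(table, alpha=alpha)
    (out / "report.txt").write_text(report(est, case_label=config.get("case_label", "Case")))
    payload = _estimate_payload(est)

    weighting = config.get("weighting")
    if weighting:
        strata_by_rid = {rid: strata_labels.get(pid, "?") for rid, pid in ledger.items()}
        tables = score_against_algorithm(adjudications, flags_by_rid, strata=strata_by_rid)
        strata_w = [
            StratumWeight(
                label=label,
                sampled_n=tables[label].n_negative if label in tables else 0,
                observed_fn=tables[label].fn if label in tables else 0,
                population_share=share,
            )
            for label, share in weighting["shares"].items()
        ]
        wres = weighted_npv(strata_w, reporting_n=float(weighting["reporting_n"]), alpha=alpha)
        payload["weighted_npv"] = dataclasses.asdict(wres)
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    manifest["stages"]["validate"] = {
        "sampled": len(sample_ids),
        "consensus_used": sum(a.consensus_used for a in adjudications),
    }
    manifest["stages"]["estimate"] = payload["reported"]
    return est
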