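"""File formats and report assembly.

Plain-text interchange: edge lists and JSON for topologies, CSV for
decision records, JSON for trial logs, behavior parameters and
analysis reports. Every artifact written by the CLI carries a
provenance block (command, seed, config) in a JSON sidecar or header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import (
    fit_beta,
    fit_hurdle,
    giving_timecourse,
    recipient_positions,
    reverse_redistribution_stats,
    wilcoxon_by_treatment,
    HurdleFit,
)
from .networks import Topology
from .simulate import GivingEvent, TrialLog


def write_topology(topo: Topology, outdir, stem: str | None = None) -> tuple[Path, Path]:
    """Write a topology as '<stem>.edges' (plain 'u v' lines) + '<stem>.json'."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or topo.label
    edge_path = outdir / f"{stem}.edges"
    json_path = outdir / f"{stem}.json"
    topo.write_edgelist(edge_path)
    json_path.write_text(topo.to_json())
    return edge_path, json_path


def read_topology(path) -> Topology:
    """Load and validate a topology JSON document."""
    return Topology.from_json(Path(path).read_text())


def write_trials(logs: list[TrialLog], path) -> None:
    """Serialize trial logs (with their topologies) to one JSON file."""
    docs = []
    for log in logs:
        docs.append(
            {
                "topology": json.loads(log.topology.to_json()),
                "seed": log.seed,
                "session": log.session,
                "stop_reason": log.stop_reason,
                "incomes_by_round": log.incomes_by_round.tolist(),
                "events": [[e.t, e.giver, e.recipient, e.amount] for e in log.events],
            }
        )
    Path(path).write_text(json.dumps(docs))


def read_trials(path) -> list[TrialLog]:
    docs = json.loads(Path(path).read_text())
    logs = []
    for doc in docs:
        topo = Topology.from_json(json.dumps(doc["topology"]))
        logs.append(
            TrialLog(
                topology=topo,
                seed=doc["seed"],
                session=doc["session"],
                stop_reason=doc["stop_reason"],
                incomes_by_round=np.array(doc["incomes_by_round"], dtype=np.int64),
                events=[GivingEvent(*e) for e in doc["events"]],
            )
        )
    return logs


# -- analysis report ------------------------------------------------------


def _hurdle_doc(fit: HurdleFit) -> dict:
    def part(p):
        return {
            "coef": {k: float(v) for k, v in p.params.items()},
            "se": {k: float(v) for k, v in p.bse.items()},
            "p": {k: float(v) for k, v in p.pvalues.items()},
            "nobs": p.nobs,
        }

    return {
        "probability": part(fit.prob),
        "amount": part(fit.amount),
        "n_records": fit.n_records,
        "n_clusters": fit.n_clusters,
        "dropped": list(fit.dropped),
    }


def analyze_experiment(records: pd.DataFrame, logs: list[TrialLog]) -> dict:
    """Run the full analysis stack on one experiment's records + logs.

    Per-treatment hurdle regressions and Beta allocation fits, the
    session-level Wilcoxon comparison of initial vs end-round Gini per
    treatment, the reverse-redistribution share with its reciprocity
    fit, and the giving time-course.
    """
    report: dict = {"n_trials": len(logs), "n_records": len(records)}
    hurdles = {}
    for label, sub in records.groupby("treatment", sort=True):
        try:
            hurdles[label] = _hurdle_doc(fit_hurdle(sub))
        except ValueError as err:
            hurdles[label] = {"error": str(err)}
    report["hurdle"] = hurdles

    betas = {}
    by_label: dict[str, list[TrialLog]] = {}
    for log in logs:
        by_label.setdefault(log.label, []).append(log)
    for label, group in sorted(by_label.items()):
        pos = recipient_positions(group)
        if pos.size >= 10:
            fit = fit_beta(pos)
            betas[label] = {"beta1": fit.beta1, "beta2": fit.beta2, "n": fit.n}
        else:
            betas[label] = {"error": f"only {pos.size} giving events"}
    report["beta"] = betas

    report["wilcoxon"] = wilcoxon_by_treatment(logs).to_dict(orient="records")

    share, recip = reverse_redistribution_stats(logs, records)
    report["reverse_redistribution"] = {
        "share": share,
        "reciprocity": _hurdle_doc(recip) if recip is not None else None,
    }
    report["timecourse"] = giving_timecourse(records).to_dict(orient="records")
    return report


def render_report(report: dict) -> str:
    """Human-readable text rendering of an analysis report."""
    lines = []
    lines.append(f"Trials: {report['n_trials']}   Records: {report['n_records']}")
    lines.append("")
    lines.append("== Hurdle regressions (cluster-robust SEs, by subject) ==")
    for label, doc in report["hurdle"].items():
        lines.append(f"-- {label} --")
        if "error" in doc:
            lines.append(f"  unfittable: {doc['error']}")
            continue
        for part in ("probability", "amount"):
            lines.append(f"  {part} part (n={doc[part]['nobs']}):")
            for term, coef in doc[part]["coef"].items():
                se = doc[part]["se"][term]
                pv = doc[part]["p"][term]
                lines.append(f"    {term:>6}: {coef: .4f} (se {se:.4f}, p {pv:.3g})")
        if doc["dropped"]:
            lines.append(f"  dropped (no variance): {', '.join(doc['dropped'])}")
    lines.append("")
    lines.append("== Beta allocation fits (recipient poverty positions) ==")
    for label, doc in report["beta"].items():
        if "error" in doc:
            lines.append(f"  {label}: {doc['error']}")
        else:
            lines.append(
                f"  {label}: beta1={doc['beta1']:.2f} beta2={doc['beta2']:.2f} (n={doc['n']})"
            )
    lines.append("")
    lines.append("== Wilcoxon signed-rank, end-round vs initial Gini (per session) ==")
    for row in report["wilcoxon"]:
        lines.append(
            f"  {row['treatment']}: W={row['W']:.1f} p={row['p']:.4f} (n={row['n_sessions']})"
        )
    rev = report["reverse_redistribution"]
    lines.append("")
    lines.append(f"== Reverse redistribution: share={rev['share']:.4f} ==")
    if rev["reciprocity"] is not None:
        rp = rev["reciprocity"]
        cp = rp["probability"]["coef"].get("received_prev")
        ca = rp["amount"]["coef"].get("received_prev")
        lines.append(
            f"  reciprocity: received_prev coef {cp:.4g} (prob part), {ca:.4g} (amount part)"
        )
    lines.append("")
    lines.append("== Giving time-course ==")
    for row in report["timecourse"]:
        lines.append(
            f"  round {int(row['round']):2d}: donors {row['prop_donating']:.3f}, "
            f"mean fraction given {row['mean_fraction_given']:.4f}"
        )
    return "\n".join(lines) + "\n"
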