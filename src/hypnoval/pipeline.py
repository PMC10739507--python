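"""End-to-end validation study: from a study manifest to report tables.

The study asks how an automatic sleep scorer compares against human scoring,
via four linked analyses, each with recording-level bootstrap inference:

1. *Majority-vote agreement*: the machine against the consensus staging of
   the manual panel (epochs without a >= 2-rater consensus are excluded).
2. *Clinical agreement*: the machine against the clinical reference staging.
3. *Direct difference*: the machine's average agreement with each technician
   minus the technicians' average agreement among themselves (all ordered
   technician pairs) -- and likewise referenced on the clinical staging.
   This uses *all* co-staged epochs, so the hard non-consensus epochs the
   majority-vote analysis discards are kept in.
4. *Macrostructure reliability*: ICC(A,1) of the ten macrostructure indices
   for machine-technician pairs vs technician-technician pairs (and against
   the clinical staging), with bootstrapped ICC differences.

Epoch retention is recomputed independently for each analysis: an analysis
uses exactly the epochs staged (non-U) by every scorer it considers.
Everything downstream of the manifest is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import STAT_NAMES, build_confusion, stats_vector
from .bootstrap import BootstrapConfig, BootstrapResult, classify_significance, cluster_bootstrap
from .consensus import majority_vote
from .hypnogram import STAGES, EmptyStagingError, Hypnogram, align_and_filter
from .icc import icc_value, interpret_icc
from .macrostructure import MACRO_INDEX_NAMES, compute_macro
from .manifest import StudyManifest, load_manifest

__all__ = ["StudyReport", "run_validation_study", "write_report"]

_PERCENT_STATS = {n for n in STAT_NAMES if n != "kappa"}


def _stat_scale(name: str) -> float:
    return 100.0 if name in _PERCENT_STATS else 1.0


def _stat_round(name: str) -> int:
    # percentages to 2 decimals, kappa (and ICC) to 4
    return 2 if name in _PERCENT_STATS else 4


@dataclass
class _RecordingData:
    """Per-recording sufficient statistics for every analysis."""

    recording_id: str
    conf_majority: np.ndarray  # ref = consensus, test = machine
    nonconsensus_row: np.ndarray  # machine stage counts on non-consensus epochs
    conf_machine_vs_tech: list[np.ndarray]  # ref = tech_i, test = machine
    conf_tech_pairs: list[np.ndarray]  # all ordered manual pairs
    conf_clin_machine: np.ndarray | None  # ref = clinical, test = machine
    conf_clin_tech: list[np.ndarray] | None  # ref = clinical, test = tech_i
    macro: np.ndarray  # (n_scorers, 10) in manifest scorer order
    accounting: dict


@dataclass
class StudyReport:
    """All output tables of one validation run plus provenance."""

    confusion_majority: pd.DataFrame
    table_majority: pd.DataFrame
    table_diff_panel: pd.DataFrame
    table_icc_panel: pd.DataFrame
    macro_table: pd.DataFrame
    confusion_clinical: pd.DataFrame | None
    table_clinical: pd.DataFrame | None
    table_diff_clinical: pd.DataFrame | None
    table_icc_clinical: pd.DataFrame | None
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "confusion_majority": self.confusion_majority,
            "table_majority": self.table_majority,
            "table_diff_panel": self.table_diff_panel,
            "table_icc_panel": self.table_icc_panel,
            "macro_table": self.macro_table,
        }
        for name in ("confusion_clinical", "table_clinical", "table_diff_clinical",
                     "table_icc_clinical"):
            df = getattr(self, name)
            if df is not None:
                out[name] = df
        return out


def _confusion_array(ref: Sequence[str], test: Sequence[str]) -> np.ndarray:
    return build_confusion(ref, test).counts


def _prepare_recording(
    hyps: dict[str, Hypnogram],
    machine: str,
    manual: tuple[str, ...],
    clinical: str | None,
    scorer_order: tuple[str, ...],
) -> _RecordingData:
    rec_id = hyps[machine].recording_id
    accounting: dict = {"recording_id": rec_id,
                        "staged_epochs": {s: h.n_epochs for s, h in hyps.items()}}

    # -- panel analyses: machine + manual raters on their common epochs
    panel_inputs = [hyps[machine]] + [hyps[t] for t in manual]
    panel = align_and_filter(panel_inputs)
    max_len = max(h.n_epochs for h in panel_inputs)
    accounting["panel_aligned"] = panel.n_epochs
    accounting["panel_dropped_truncation_or_u"] = max_len - panel.n_epochs

    consensus = majority_vote(panel.restrict(manual))
    machine_col = panel.column(machine)
    kept = [i for i, s in enumerate(consensus.consensus_stages) if s is not None]
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    nonconsensus_row = np.zeros(len(STAGES), dtype=np.int64)
    for i, s in enumerate(consensus.consensus_stages):
        if s is None:
            nonconsensus_row[stage_idx[machine_col[i]]] += 1
    conf_majority = _confusion_array(
        consensus.retained_stages, [machine_col[i] for i in kept]
    )
    accounting["consensus_full"] = consensus.n_full_agreement
    accounting["consensus_partial"] = consensus.n_partial_agreement
    accounting["consensus_none"] = consensus.n_nonconsensus

    tech_cols = {t: panel.column(t) for t in manual}
    conf_machine_vs_tech = [
        _confusion_array(tech_cols[t], machine_col) for t in manual
    ]
    conf_tech_pairs = [
        _confusion_array(tech_cols[a], tech_cols[b])
        for a in manual for b in manual if a != b
    ]

    # -- clinical analyses: each scorer aligned pairwise with the clinical staging
    conf_clin_machine = conf_clin_tech = None
    if clinical is not None:
        pair = align_and_filter([hyps[clinical], hyps[machine]])
        conf_clin_machine = _confusion_array(pair.column(clinical), pair.column(machine))
        accounting["clinical_machine_aligned"] = pair.n_epochs
        conf_clin_tech = []
        for t in manual:
            pair_t = align_and_filter([hyps[clinical], hyps[t]])
            conf_clin_tech.append(
                _confusion_array(pair_t.column(clinical), pair_t.column(t))
            )

    macro = np.vstack([compute_macro(hyps[s]).to_vector() for s in scorer_order])
    return _RecordingData(
        recording_id=rec_id,
        conf_majority=conf_majority,
        nonconsensus_row=nonconsensus_row,
        conf_machine_vs_tech=conf_machine_vs_tech,
        conf_tech_pairs=conf_tech_pairs,
        conf_clin_machine=conf_clin_machine,
        conf_clin_tech=conf_clin_tech,
        macro=macro,
        accounting=accounting,
    )


def _avg_pair_stats(stacks: list[np.ndarray], idx: np.ndarray) -> np.ndarray:
    """Average the 17-statistic vector over pair confusion stacks, NaN-skipping."""
    vecs = np.vstack([stats_vector(st[idx].sum(axis=0)) for st in stacks])
    defined = (~np.isnan(vecs)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(defined > 0, np.nansum(vecs, axis=0) / np.maximum(defined, 1), np.nan)


def _stats_table(
    result: BootstrapResult, plug_in: np.ndarray, names: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for i, name in enumerate(names):
        scale, nd = _stat_scale(name), _stat_round(name)
        rows.append({
            "statistic": name,
            "plug_in": round(plug_in[i] * scale, nd),
            "median": round(result.point[i] * scale, nd),
            "ci_lower": round(result.ci_lower[i] * scale, nd),
            "ci_upper": round(result.ci_upper[i] * scale, nd),
            "n_defined_resamples": int(result.n_defined[i]),
        })
    return pd.DataFrame(rows)


def _diff_table(result: BootstrapResult, sections: Sequence[str]) -> pd.DataFrame:
    """Three stacked 17-vectors (two averages + their difference) as one table."""
    rows = []
    k = len(STAT_NAMES)
    for b, section in enumerate(sections):
        is_diff = section == "difference"
        for i, name in enumerate(STAT_NAMES):
            j = b * k + i
            scale, nd = _stat_scale(name), _stat_round(name)
            row = {
                "section": section,
                "statistic": name,
                "median": round(result.point[j] * scale, nd),
                "ci_lower": round(result.ci_lower[j] * scale, nd),
                "ci_upper": round(result.ci_upper[j] * scale, nd),
            }
            if is_diff:
                row["significant"] = classify_significance(
                    result.ci_lower[j], result.ci_upper[j]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _icc_table(result: BootstrapResult, sections: Sequence[str]) -> pd.DataFrame:
    rows = []
    k = len(MACRO_INDEX_NAMES)
    for i, index in enumerate(MACRO_INDEX_NAMES):
        row: dict = {"index": index}
        for b, section in enumerate(sections):
            j = b * k + i
            row[f"{section}_median"] = round(result.point[j], 4)
            row[f"{section}_ci_lower"] = round(result.ci_lower[j], 4)
            row[f"{section}_ci_upper"] = round(result.ci_upper[j], 4)
            if section == "difference":
                row["significant"] = classify_significance(
                    result.ci_lower[j], result.ci_upper[j]
                )
            else:
                med = result.point[j]
                row[f"{section}_interpretation"] = (
                    interpret_icc(med) if not np.isnan(med) else None
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _confusion_report(
    pooled: np.ndarray, nonconsensus: np.ndarray | None
) -> pd.DataFrame:
    """Printed-table layout: reference rows (+ non-consensus) x test columns."""
    rows = list(STAGES)
    data = pooled.copy()
    if nonconsensus is not None:
        data = np.vstack([data, nonconsensus])
        rows.append("Non-consensus")
    df = pd.DataFrame(data, index=rows, columns=list(STAGES))
    df["Total"] = df.sum(axis=1)
    df.loc["Total"] = df.sum(axis=0)
    df.index.name = "reference"
    return df


def run_validation_study(
    manifest: StudyManifest | str | Path,
    n_resamples: int | None = None,
    seed: int | None = None,
) -> StudyReport:
    """Execute the full validation analysis described in the module docstring.

    ``n_resamples`` and ``seed`` override the manifest's bootstrap block.
    Recordings whose analysis sets retain zero epochs are skipped with a
    note in the provenance.
    """
    if not isinstance(manifest, StudyManifest):
        manifest = load_manifest(manifest)
    manifest.validate()
    machine = manifest.automatic_scorer
    manual = manifest.manual_scorers
    clinical = manifest.clinical_scorer
    scorer_order = tuple(manifest.scorers)

    boot = dict(manifest.bootstrap)
    if n_resamples is not None:
        boot["n_resamples"] = n_resamples
    if seed is not None:
        boot["seed"] = seed
    n_res = int(boot.get("n_resamples", 10_000))
    run_seed = int(boot.get("seed", 0))

    recs: list[_RecordingData] = []
    skipped: list[str] = []
    for entry in manifest.recordings:
        hyps = {s: entry.load(s) for s in manifest.scorers}
        try:
            recs.append(_prepare_recording(hyps, machine, manual, clinical, scorer_order))
        except EmptyStagingError as err:
            skipped.append(f"{entry.recording_id}: {err}")
    if not recs:
        raise ValueError("no recording yielded a non-empty analysis set")
    n_rec = len(recs)
    indices = list(range(n_rec))

    # stacked per-recording sufficient statistics (bootstrap hot path)
    maj_stack = np.stack([r.conf_majority for r in recs])
    mvt_stacks = [np.stack([r.conf_machine_vs_tech[j] for r in recs])
                  for j in range(len(manual))]
    tp_stacks = [np.stack([r.conf_tech_pairs[j] for r in recs])
                 for j in range(len(recs[0].conf_tech_pairs))]
    macro_stack = np.stack([r.macro for r in recs])
    scorer_pos = {s: i for i, s in enumerate(scorer_order)}

    ss = np.random.SeedSequence(run_seed)
    seeds = ss.spawn(6)

    def stat_majority(items: list[int]) -> np.ndarray:
        idx = np.asarray(items)
        return stats_vector(maj_stack[idx].sum(axis=0))

    def stat_diff_panel(items: list[int]) -> np.ndarray:
        idx = np.asarray(items)
        machine_avg = _avg_pair_stats(mvt_stacks, idx)
        panel_avg = _avg_pair_stats(tp_stacks, idx)
        return np.concatenate([machine_avg, panel_avg, machine_avg - panel_avg])

    def _icc_block(sel: np.ndarray, pairs_a: list, pairs_b: list) -> np.ndarray:
        k = len(MACRO_INDEX_NAMES)
        out = np.empty(3 * k)
        for i in range(k):
            a_vals = [icc_value(sel[:, p, i], sel[:, q, i]) for p, q in pairs_a]
            b_vals = [icc_value(sel[:, p, i], sel[:, q, i]) for p, q in pairs_b]
            a = np.nanmean(a_vals) if not np.all(np.isnan(a_vals)) else np.nan
            b = np.nanmean(b_vals) if not np.all(np.isnan(b_vals)) else np.nan
            out[i], out[k + i], out[2 * k + i] = a, b, a - b
        return out

    mach_pairs = [(scorer_pos[machine], scorer_pos[t]) for t in manual]
    tech_pairs = [(scorer_pos[a], scorer_pos[b])
                  for i, a in enumerate(manual) for b in manual[i + 1:]]

    def stat_icc_panel(items: list[int]) -> np.ndarray:
        return _icc_block(macro_stack[np.asarray(items)], mach_pairs, tech_pairs)

    cfg = lambda s: BootstrapConfig(n_resamples=n_res, seed=s)
    with np.errstate(invalid="ignore"):
        res_majority = cluster_bootstrap(indices, stat_majority, cfg(seeds[0]))
        res_diff_panel = cluster_bootstrap(indices, stat_diff_panel, cfg(seeds[1]))
        res_icc_panel = cluster_bootstrap(indices, stat_icc_panel, cfg(seeds[2]))

    pooled_majority = maj_stack.sum(axis=0)
    table_majority = _stats_table(res_majority, stats_vector(pooled_majority), STAT_NAMES)
    confusion_majority = _confusion_report(
        pooled_majority, np.sum([r.nonconsensus_row for r in recs], axis=0)
    )
    table_diff_panel = _diff_table(
        res_diff_panel, ("machine_vs_panel", "within_panel", "difference")
    )
    table_icc_panel = _icc_table(
        res_icc_panel, ("machine_vs_panel", "within_panel", "difference")
    )

    confusion_clinical = table_clinical = table_diff_clinical = table_icc_clinical = None
    if clinical is not None:
        clin_m_stack = np.stack([r.conf_clin_machine for r in recs])
        clin_t_stacks = [np.stack([r.conf_clin_tech[j] for r in recs])
                         for j in range(len(manual))]
        clin_mach_pairs = [(scorer_pos[machine], scorer_pos[clinical])]
        clin_tech_pairs = [(scorer_pos[t], scorer_pos[clinical]) for t in manual]

        def stat_clinical(items: list[int]) -> np.ndarray:
            return stats_vector(clin_m_stack[np.asarray(items)].sum(axis=0))

        def stat_diff_clinical(items: list[int]) -> np.ndarray:
            idx = np.asarray(items)
            machine_v = stats_vector(clin_m_stack[idx].sum(axis=0))
            tech_avg = _avg_pair_stats(clin_t_stacks, idx)
            return np.concatenate([machine_v, tech_avg, machine_v - tech_avg])

        def stat_icc_clinical(items: list[int]) -> np.ndarray:
            return _icc_block(
                macro_stack[np.asarray(items)], clin_mach_pairs, clin_tech_pairs
            )

        with np.errstate(invalid="ignore"):
            res_clinical = cluster_bootstrap(indices, stat_clinical, cfg(seeds[3]))
            res_diff_clin = cluster_bootstrap(indices, stat_diff_clinical, cfg(seeds[4]))
            res_icc_clin = cluster_bootstrap(indices, stat_icc_clinical, cfg(seeds[5]))
        pooled_clin = clin_m_stack.sum(axis=0)
        table_clinical = _stats_table(res_clinical, stats_vector(pooled_clin), STAT_NAMES)
        confusion_clinical = _confusion_report(pooled_clin, None)
        table_diff_clinical = _diff_table(
            res_diff_clin, ("machine_vs_clinical", "technicians_vs_clinical", "difference")
        )
        table_icc_clinical = _icc_table(
            res_icc_clin, ("machine_vs_clinical", "technicians_vs_clinical", "difference")
        )

    macro_rows = []
    for r in recs:
        for s in scorer_order:
            row = {"recording_id": r.recording_id, "scorer_id": s}
            row.update({
                name: round(v, 4)
                for name, v in zip(MACRO_INDEX_NAMES, r.macro[scorer_pos[s]])
            })
            macro_rows.append(row)
    macro_table = pd.DataFrame(macro_rows)

    total_panel = int(sum(r.accounting["panel_aligned"] for r in recs))
    n_full = int(sum(r.accounting["consensus_full"] for r in recs))
    n_partial = int(sum(r.accounting["consensus_partial"] for r in recs))
    n_non = int(sum(r.accounting["consensus_none"] for r in recs))
    provenance = {
        "n_recordings": n_rec,
        "skipped_recordings": skipped,
        "seed": run_seed,
        "n_resamples": n_res,
        "machine_scorer": machine,
        "manual_scorers": list(manual),
        "clinical_scorer": clinical,
        "epoch_accounting": {
            "panel_epochs_staged_by_all": total_panel,
            "consensus_full": n_full,
            "consensus_partial": n_partial,
            "consensus_none": n_non,
            "consensus_full_pct": round(100.0 * n_full / total_panel, 2),
            "consensus_partial_pct": round(100.0 * n_partial / total_panel, 2),
            "consensus_none_pct": round(100.0 * n_non / total_panel, 2),
        },
        "per_recording": [r.accounting for r in recs],
    }
    return StudyReport(
        confusion_majority=confusion_majority,
        table_majority=table_majority,
        table_diff_panel=table_diff_panel,
        table_icc_panel=table_icc_panel,
        macro_table=macro_table,
        confusion_clinical=confusion_clinical,
        table_clinical=table_clinical,
        table_diff_clinical=table_diff_clinical,
        table_icc_clinical=table_icc_clinical,
        provenance=provenance,
    )


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write per-table CSVs, a machine-readable JSON report and a run log.

    Output is deterministic for a fixed manifest and seed (no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = report.tables()
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=name.startswith("confusion"))
    payload = {"provenance": report.provenance}
    for name, df in tables.items():
        if name.startswith("confusion"):
            payload[name] = {str(k): v for k, v in df.to_dict(orient="index").items()}
        else:
            payload[name] = json.loads(df.to_json(orient="records"))
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    lines = [f"recordings analysed: {report.provenance['n_recordings']}"]
    for note in report.provenance["skipped_recordings"]:
        lines.append(f"skipped: {note}")
    for acc in report.provenance["per_recording"]:
        lines.append(
            f"{acc['recording_id']}: staged={acc['staged_epochs']} "
            f"panel_aligned={acc['panel_aligned']} "
            f"dropped={acc['panel_dropped_truncation_or_u']} "
            f"consensus full/partial/none="
            f"{acc['consensus_full']}/{acc['consensus_partial']}/{acc['consensus_none']}"
        )
    (out_dir / "run.log").write_text("\n".join(lines) + "\n")
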