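"""Pipeline orchestration: features -> variability -> distinctiveness.

:func:`run_pipeline` drives the whole analysis from a :class:`RunConfig`
and writes a report bundle into the output directory:

* ``features.csv`` — one row per call segment, metadata plus 20 parameters;
* ``variability.csv`` — per call type x parameter CV/PIC statistics with
  overall rows;
* ``friedman.csv`` — cross-call-type comparisons (Friedman tests of the
  CV_intra / CV_inter / PIC matrices, and the arcsine-LMM comparing
  leave-one-out assignment rates);
* ``table3_report.csv`` — the per-call-type distinctiveness summary
  (n, DFA %, P1, C-DFA %, P2, chance, functions, Wilks lambda, chi2, df, p,
  significant parameters) plus per-caller rows;
* ``pdfa.json`` — observed rates, p-values and full permutation
  distributions;
* ``run.log`` — seed, config hash, library versions and per-stage row
  counts, so dataset attrition through the inclusion filters is auditable.

Identical config and seed give byte-identical CSV/JSON payloads.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio as au
from . import distinctiveness as dist
from . import features as feat
from . import variability as vy
from .config import RunConfig

__all__ = ["run_pipeline", "compute_feature_table"]

log = logging.getLogger("vocalid")

_META_COLS = [
    "segment_id",
    "caller_id",
    "call_type",
    "sequence_id",
    "timestamp",
    "audio_path",
    "quality_ok",
]


def _read_meta(path: str | Path) -> list[au.CallRecord]:
    meta = pd.read_csv(path)
    missing = set(_META_COLS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata CSV lacks columns: {sorted(missing)}")
    records = []
    for row in meta.itertuples(index=False):
        records.append(
            au.CallRecord(
                segment_id=str(row.segment_id),
                caller_id=str(row.caller_id),
                call_type=str(row.call_type),
                sequence_id=str(row.sequence_id),
                timestamp=float(row.timestamp),
                audio_path=str(row.audio_path),
                quality_ok=bool(row.quality_ok),
            )
        )
    return records


def compute_feature_table(records, audio_dir: str | Path, config: RunConfig) -> pd.DataFrame:
    """Audio -> feature table for pre-filtered call records."""
    audio_dir = Path(audio_dir)
    rows = []
    for rec in records:
        w = au.read_wav(audio_dir / rec.audio_path)
        target = au.select_band_rate(rec.call_type, config.rate_map)
        w = au.resample(w, min(target, w.rate))
        spec = au.spectrogram(w, window=config.window)
        fv = feat.extract_features(
            spec,
            band_threshold_db=config.band_threshold_db,
            tonal_cut=config.tonal_cut,
            noisy_cut=config.noisy_cut,
        )
        rows.append(
            {
                "segment_id": rec.segment_id,
                "caller_id": rec.caller_id,
                "call_type": rec.call_type,
                "sequence_id": rec.sequence_id,
                "timestamp": rec.timestamp,
                **fv.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def _load_features(config: RunConfig) -> pd.DataFrame:
    if config.features_csv:
        table = pd.read_csv(config.features_csv)
        needed = {"segment_id", "caller_id", "call_type", *feat.FEATURE_NAMES}
        missing = needed - set(table.columns)
        if missing:
            raise ValueError(f"feature CSV lacks columns: {sorted(missing)}")
        if "quality_ok" in table.columns:
            table = table[table["quality_ok"].astype(bool)]
        log.info("loaded %d feature rows from %s", len(table), config.features_csv)
        return table
    if not (config.meta_csv and config.audio_dir):
        raise ValueError("config needs either features_csv or meta_csv + audio_dir")
    records = _read_meta(config.meta_csv)
    log.info("metadata: %d call segments", len(records))
    kept = au.filter_call_records(
        records, min_gap_s=config.min_gap_s, min_calls=config.min_calls
    )
    log.info("after inclusion filters: %d call segments", len(kept))
    return compute_feature_table(kept, config.audio_dir, config)


def _eligible(table: pd.DataFrame, call_type: str, config: RunConfig) -> pd.DataFrame:
    """Rows of one call type restricted to callers meeting min_calls, with
    listwise-complete feature vectors."""
    sub = table[table["call_type"] == call_type].dropna(subset=list(feat.FEATURE_NAMES))
    counts = sub.groupby("caller_id").size()
    keep = counts[counts >= config.min_calls].index
    return sub[sub["caller_id"].isin(keep)]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle as Python objects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "seed=%d config=%s numpy=%s pandas=%s",
            config.seed,
            config.digest(),
            np.__version__,
            pd.__version__,
        )
        table = _load_features(config)
        table = table.sort_values(["call_type", "caller_id", "segment_id"]).reset_index(
            drop=True
        )
        table.to_csv(out / "features.csv", index=False, float_format="%.6g")

        analyzable = {}
        for ctype in config.call_types:
            sub = _eligible(table, ctype, config)
            n_callers = sub["caller_id"].nunique()
            log.info("%s: %d rows, %d eligible callers", ctype, len(sub), n_callers)
            if n_callers >= 2:
                analyzable[ctype] = sub
        if not analyzable:
            counts = table.groupby(["call_type", "caller_id"]).size().to_dict()
            raise ValueError(f"nothing to analyze; per-(type, caller) counts: {counts}")

        # ---- variability ------------------------------------------------
        var_rows, summaries = [], {}
        for ctype, sub in analyzable.items():
            summ = vy.variability_summary(sub, ctype)
            summaries[ctype] = summ
            pp = summ.per_parameter.reset_index()
            pp.insert(0, "call_type", ctype)
            var_rows.append(pp)
            var_rows.append(
                pd.DataFrame(
                    [
                        {
                            "call_type": ctype,
                            "parameter": "OVERALL",
                            "cv_inter": summ.cv_inter_mean,
                            "cv_intra": summ.cv_intra_mean,
                            "pic": summ.overall_pic,
                        }
                    ]
                )
            )
        var_table = pd.concat(var_rows, ignore_index=True)
        var_table.to_csv(out / "variability.csv", index=False, float_format="%.6g")

        fried_rows = []
        if len(summaries) >= 2:
            for stat in ("cv_intra", "cv_inter", "pic"):
                mat = pd.DataFrame(
                    {ct: s.per_parameter[stat] for ct, s in summaries.items()}
                ).dropna()
                if len(mat) >= 2:
                    chi2, df, p = vy.friedman_test(mat.to_numpy())
                    fried_rows.append(
                        {"test": f"friedman_{stat}", "statistic": chi2, "df": df,
                         "n_blocks": len(mat), "p": p}
                    )

        # ---- distinctiveness --------------------------------------------
        seeds = np.random.SeedSequence(config.seed).generate_state(len(analyzable))
        report_rows, pdfa_out, acc_rows = [], {}, []
        for (ctype, sub), ct_seed in zip(sorted(analyzable.items()), seeds):
            ct_seed = int(ct_seed % (2**31))
            try:
                dfa = dist.stepwise_dfa(
                    sub,
                    call_type=ctype,
                    f_to_enter=config.f_to_enter,
                    f_to_remove=config.f_to_remove,
                )
            except ValueError as exc:
                log.warning("%s: DFA failed (%s)", ctype, exc)
                continue
            pres = dist.pdfa(
                sub,
                parameters=dfa.selected_parameters,
                n_selections=config.n_selections,
                n_permutations=config.n_permutations,
                seed=ct_seed,
                call_type=ctype,
            )
            strong = dfa.loadings.loc[
                dfa.loadings.abs().max(axis=1) > config.loading_cutoff
            ].index.tolist()
            strong = sorted(set(strong) | set(dfa.selected_parameters))
            lmm = dist.lmm_parameter_significance(sub, strong, alpha=config.alpha)
            significant = lmm.index[lmm["reject"]].tolist()

            report_rows.append(
                {
                    "call_type": ctype,
                    "caller_id": "ALL",
                    "n": dfa.n_total,
                    "dfa_pct": dfa.resub_overall,
                    "p1": pres.p1,
                    "cdfa_pct": dfa.loo_overall,
                    "p2": pres.p2,
                    "chance_pct": dfa.chance,
                    "n_functions": dfa.n_functions,
                    "wilks_lambda": dfa.wilks_lambda,
                    "df": dfa.df,
                    "chi2": dfa.chi2,
                    "p": dfa.p,
                    "n_lmm": len(lmm),
                    "significant_parameters": " ".join(significant),
                }
            )
            for caller in dfa.callers:
                report_rows.append(
                    {
                        "call_type": ctype,
                        "caller_id": caller,
                        "n": dfa.n_per_caller[caller],
                        "dfa_pct": dfa.resub_per_caller[caller],
                        "cdfa_pct": dfa.loo_per_caller[caller],
                        "chance_pct": dfa.chance,
                    }
                )
                loo_pc = dfa.loo_per_caller[caller]
                if np.isfinite(loo_pc):
                    acc_rows.append(
                        {
                            "caller_id": caller,
                            "call_type": ctype,
                            "proportion": loo_pc / 100.0,
                            "n_calls": dfa.n_per_caller[caller],
                        }
                    )
            pdfa_out[ctype] = {
                "observed_fitting": pres.observed_fitting,
                "observed_cv": pres.observed_cv,
                "p1": pres.p1,
                "p2": pres.p2,
                "n_selections": pres.n_selections,
                "n_permutations": pres.n_permutations,
                "seed": pres.seed,
                "balanced": pres.balanced,
                "n_per_selection": pres.n_per_selection,
                "selected_parameters": dfa.selected_parameters,
                "null_fitting": [round(v, 6) for v in pres.null_fitting],
                "null_cv": [round(v, 6) for v in pres.null_cv],
            }

        if not report_rows:
            raise ValueError("nothing to analyze: no call type supported a DFA")
        report = pd.DataFrame(report_rows)
        report.to_csv(out / "table3_report.csv", index=False, float_format="%.6g")
        (out / "pdfa.json").write_text(json.dumps(pdfa_out, indent=1, sort_keys=True))

        crosstype = None
        acc = pd.DataFrame(acc_rows)
        if not acc.empty and acc["call_type"].nunique() >= 2:
            f_stat, (df1, df2), p = dist.compare_call_types(acc)
            crosstype = {"F": f_stat, "df_num": df1, "df_den": df2, "p": p}
            fried_rows.append(
                {"test": "crosstype_lmm_arcsine", "statistic": f_stat,
                 "df": df1, "n_blocks": df2, "p": p}
            )
        pd.DataFrame(fried_rows).to_csv(
            out / "friedman.csv", index=False, float_format="%.6g"
        )
        log.info("report written to %s", out)
        return {
            "features": table,
            "variability": var_table,
            "report": report,
            "pdfa": pdfa_out,
            "friedman": pd.DataFrame(fried_rows),
            "crosstype": crosstype,
        }
    finally:
        log.removeHandler(handler)
        handler.close()
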