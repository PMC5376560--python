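"""End-to-end orchestration: cohort -> preprocessing -> network -> statistics.

The pipeline runs either on a synthetic cohort specification or on files
(phenotype table, per-subject series and motion TSVs).  Stages execute in
the fixed order

    motion QC -> discard -> detrend -> bandpass -> nuisance regression
    -> connectivity -> degree centrality -> median split
    -> per-group hub identification and edge screening
    -> demographic statistics

with every intermediate persisted under the output directory, and the whole
run is a deterministic function of the configuration (a config hash and the
seed are recorded in the report).  Group-level association analyses are run
strictly within each age subgroup; no pooled between-group connectivity
contrast is computed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import network as net
from . import stats as mstats
from .motion import MotionTrace, check_exclusion, compare_group_motion
from .preprocess import NuisanceSet, ROITimeSeries, default_preprocess
from .synthetic import (
    CohortSpec,
    generate_cohort,
    generate_nuisance_signals,
)

logger = logging.getLogger("masticnet")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and parameters for one full run.

    Exactly one of ``synthetic`` or the file-input triple
    (``phenotypes_path``, ``series_dir``, ``motion_dir``) must be supplied.
    """

    out_dir: str
    synthetic: CohortSpec | None = None
    phenotypes_path: str | None = None
    series_dir: str | None = None
    motion_dir: str | None = None
    n_discard: int = 3
    low_hz: float = 0.01
    high_hz: float = 0.08
    trans_limit_mm: float = 1.5
    rot_limit_deg: float = 1.5
    alpha: float = 0.05
    t_mode: str = "welch"

    def __post_init__(self) -> None:
        have_files = all(
            x is not None for x in (self.phenotypes_path, self.series_dir, self.motion_dir)
        )
        if (self.synthetic is None) == (not have_files):
            raise ValueError(
                "supply exactly one of: a synthetic CohortSpec, or all of "
                "phenotypes_path + series_dir + motion_dir"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            return o

        payload = enc(self)
        payload.pop("out_dir", None)  # output location does not change the science
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """All run-level results; every statistic is recomputable from the
    intermediates persisted under ``out_dir``."""

    out_dir: str
    demographics: pd.DataFrame
    demographic_tests: dict
    motion_qc: pd.DataFrame
    motion_tests: dict
    excluded_subjects: list[str]
    group_split: dict
    hub_tables: dict[str, pd.DataFrame]
    edge_tables: dict[str, pd.DataFrame]
    dc_by_subject: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _load_cohort(config: PipelineConfig):
    if config.synthetic is not None:
        logger.info("generating synthetic cohort (n=%d, seed=%d)",
                    config.synthetic.n_subjects, config.synthetic.seed)
        phenos, series, motion, gt = generate_cohort(config.synthetic)
        return mio.phenotypes_to_frame(phenos), series, motion, gt
    phen = mio.read_phenotypes(config.phenotypes_path)
    series = {}
    motion = {}
    for sid in phen["subject_id"]:
        series[sid] = mio.read_series(Path(config.series_dir) / f"{sid}.tsv")
        motion[sid] = mio.read_motion(Path(config.motion_dir) / f"{sid}.tsv")
    labels = None
    for sid, s in series.items():
        if labels is None:
            labels = s.node_labels
        elif s.node_labels != labels:
            raise ValueError(f"subject {sid!r}: node labels differ from the first subject")
    return phen, series, motion, None


def _subject_nuisance(
    config: PipelineConfig, sid: str, motion: MotionTrace, gt
) -> NuisanceSet | None:
    """Six motion parameters, plus synthetic ventricle/white-matter signals
    when the cohort is generated (their per-subject seeds are on record).
    All regressors are trimmed to the post-discard length."""
    reg = motion.data[config.n_discard:, :]
    names = list(mio.MOTION_COLUMNS)
    if gt is not None:
        extra = generate_nuisance_signals(
            motion.n_timepoints, seed=(gt.subject_seeds[sid] + 2) % (2**31)
        )
        reg = np.column_stack([reg, extra.to_numpy()[config.n_discard:, :]])
        names += list(extra.columns)
    # constant regressors (e.g. a motionless trace) are collinear with the
    # intercept; drop them rather than failing the whole subject
    keep = np.ptp(reg, axis=0) > 0
    if not keep.any():
        return None
    return NuisanceSet(
        regressors=reg[:, keep],
        names=tuple(n for n, k in zip(names, keep) if k),
    )


def _demographics(phen: pd.DataFrame, groups: dict, t_mode: str) -> tuple[pd.DataFrame, dict]:
    phen = phen.assign(split_group=[groups[s] for s in phen["subject_id"]])
    rows = []
    for name, sub in (("total", phen),
                      ("older", phen[phen.split_group == "older"]),
                      ("younger", phen[phen.split_group == "younger"])):
        rows.append(
            {
                "group": name,
                "n": len(sub),
                "n_male": int((sub.gender == "M").sum()),
                "n_female": int((sub.gender == "F").sum()),
                "age_mean": sub.age.mean(),
                "age_sd": sub.age.std(ddof=1),
                "age_min": sub.age.min(),
                "age_max": sub.age.max(),
                "mpi_mean": sub.mpi.mean(),
                "mpi_sd": sub.mpi.std(ddof=1),
                "mpi_min": sub.mpi.min(),
                "mpi_max": sub.mpi.max(),
            }
        )
    demo = pd.DataFrame(rows)
    older = phen[phen.split_group == "older"]
    younger = phen[phen.split_group == "younger"]
    gender_table = [
        [int((older.gender == "M").sum()), int((older.gender == "F").sum())],
        [int((younger.gender == "M").sum()), int((younger.gender == "F").sum())],
    ]
    chi2, df_chi, p_chi = mstats.chi_square_2x2(gender_table)
    t_mpi, df_mpi, p_mpi = mstats.two_sample_t(older.mpi, younger.mpi, mode=t_mode)
    t_age, df_age, p_age = mstats.two_sample_t(older.age, younger.age, mode=t_mode)
    r_all, p_all = mstats.pearson_correlation(phen.age, phen.mpi)
    r_old, p_old = mstats.pearson_correlation(older.age, older.mpi)
    r_young, p_young = mstats.pearson_correlation(younger.age, younger.mpi)
    tests = {
        "gender_chi2": {"chi2": chi2, "df": df_chi, "p": p_chi, "table": gender_table},
        "mpi_t": {"t": t_mpi, "df": df_mpi, "p": p_mpi, "mode": t_mode},
        "age_t": {"t": t_age, "df": df_age, "p": p_age, "mode": t_mode},
        "age_mpi_pearson": {
            "total": {"r": r_all, "p": p_all},
            "older": {"r": r_old, "p": p_old},
            "younger": {"r": r_young, "p": p_young},
        },
    }
    return demo, tests


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and persist every intermediate.

    Subjects failing the motion-exclusion check are reported and dropped
    before any statistics.  Raises with the stage name and subject id on any
    stage failure.
    """
    out = Path(config.out_dir)
    for sub in ("series", "connectivity", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    phen, series, motion, gt = _load_cohort(config)
    mio.write_phenotypes(phen, out / "phenotypes.tsv")
    if gt is not None:
        mio.write_ground_truth(gt, out / "ground_truth.json")

    # ---- motion QC -------------------------------------------------------
    qc_rows = []
    summaries = {}
    for sid in phen["subject_id"]:
        s = check_exclusion(motion[sid], config.trans_limit_mm, config.rot_limit_deg)
        summaries[sid] = s
        qc_rows.append({"subject_id": sid, **dataclasses.asdict(s)})
        mio.write_motion(motion[sid], out / "series" / f"{sid}_motion.tsv")
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "tables" / "motion_qc.tsv", sep="\t", index=False)
    excluded = qc.loc[qc.excluded, "subject_id"].tolist()
    if excluded:
        logger.warning("excluding %d subject(s) for motion: %s", len(excluded), excluded)
    phen = phen[~phen.subject_id.isin(excluded)].reset_index(drop=True)
    if len(phen) < 8:
        raise RuntimeError("stage motion_qc: fewer than 8 subjects survive exclusion")

    # ---- preprocessing + network ----------------------------------------
    dc_rows, weight_rows, edge_cols = [], [], None
    for sid in phen["subject_id"]:
        try:
            nuis = _subject_nuisance(config, sid, motion[sid], gt)
            prep = default_preprocess(
                series[sid], nuisance=nuis, n_discard=config.n_discard,
                low_hz=config.low_hz, high_hz=config.high_hz,
            )
            mio.write_series(prep, out / "series" / f"{sid}_preprocessed.tsv")
            cm = net.compute_connectivity(prep, clip=True)
            mio.write_connectivity(cm, out / "connectivity" / sid)
            edges = net.flatten_edges(cm)
            mio.write_edge_list(edges, out / "connectivity" / f"{sid}_edges.tsv")
            dc_rows.append(net.degree_centrality(cm).dc)
            weight_rows.append([e.weight for e in edges])
            if edge_cols is None:
                edge_cols = [f"{e.node_i}--{e.node_j}" for e in edges]
        except Exception as exc:  # re-raise with stage context
            raise RuntimeError(f"stage preprocess/network failed for subject {sid!r}: {exc}") from exc

    node_labels = series[phen["subject_id"].iloc[0]].node_labels
    dc_by_subject = pd.DataFrame(dc_rows, index=phen["subject_id"].tolist(), columns=node_labels)
    weights_by_subject = pd.DataFrame(
        weight_rows, index=phen["subject_id"].tolist(), columns=edge_cols
    )
    dc_by_subject.to_csv(out / "tables" / "degree_centrality.tsv", sep="\t")
    weights_by_subject.to_csv(out / "tables" / "edge_weights.tsv", sep="\t")

    # ---- grouping and group statistics ----------------------------------
    split = mstats.median_split(phen)
    groups = split.assignment
    motion_tests = {}
    for modality in ("translation", "rotation"):
        older_s = [summaries[s] for s in phen.subject_id if groups[s] == "older"]
        younger_s = [summaries[s] for s in phen.subject_id if groups[s] == "younger"]
        t, df, p = compare_group_motion(older_s, younger_s, modality=modality, mode=config.t_mode)
        motion_tests[modality] = {"t": t, "df": df, "p": p}

    hub_tables, edge_tables = {}, {}
    for group in ("older", "younger"):
        members = phen[[groups[s] == group for s in phen.subject_id]]
        hubs = mstats.identify_hubs(dc_by_subject, members, alpha=config.alpha)
        screen = mstats.screen_edges(weights_by_subject, members, alpha=config.alpha)
        mio.write_hub_table(hubs, out / "tables" / f"hubs_{group}.tsv")
        mio.write_edge_table(screen, out / "tables" / f"edges_{group}.tsv")
        hub_tables[group] = hubs
        edge_tables[group] = screen

    demo, demo_tests = _demographics(phen, groups, config.t_mode)
    demo.to_csv(out / "tables" / "demographics.tsv", sep="\t", index=False)

    import scipy
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.synthetic.seed if config.synthetic is not None else None,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    report = RunReport(
        out_dir=str(out),
        demographics=demo,
        demographic_tests=demo_tests,
        motion_qc=qc,
        motion_tests=motion_tests,
        excluded_subjects=excluded,
        group_split={"threshold_age": split.threshold_age, "assignment": groups},
        hub_tables=hub_tables,
        edge_tables=edge_tables,
        dc_by_subject=dc_by_subject,
        provenance=provenance,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "provenance": provenance,
                "demographic_tests": mio._jsonable(demo_tests),
                "motion_tests": mio._jsonable(motion_tests),
                "excluded_subjects": excluded,
                "group_split": mio._jsonable(report.group_split),
            },
            fh,
            indent=1,
        )
    logger.info("run complete: %s", out)
    return report
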