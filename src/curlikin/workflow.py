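"""End-to-end orchestration of the analysis pipeline.

``run_pipeline`` drives simulate -> kinetics -> spectra -> binding ->
mobility -> motifs -> correlate on a homolog panel and writes per-stage
CSV tables, a combined summary and a run log.  Everything is
deterministic given the config seed.

The bundled demo panel is synthetic and encodes the central qualitative
relationship of the study system: slow-aggregating homologs (long ThT lag)
carry a larger dimer fraction at 0 h and a more compact (smaller)
molecular-weight-normalized dimer CCS, so the panel-level Spearman
correlations come out positive for lag vs % dimer and negative for lag vs
normalized CCS.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .binding import (
    KdEstimate,
    TitrationReplicate,
    estimate_kd,
    fit_response_calibration,
)
from .kinetics import SigmoidParams, fit_sigmoid, summarize_replicates
from .mobility import ccs_from_drift, ccs_uncertainty, fit_ccs_calibration, normalized_ccs
from .motifs import ProteinSequence, find_curli_repeats, percent_identity
from .spectra import assign_peaks, percent_dimer
from .synth import (
    HomologTruth,
    NoiseModel,
    generate_homolog_panel,
    generate_titration_dataset,
)
from . import io as cio

__all__ = [
    "AnalysisConfig",
    "CorrelationResult",
    "PipelineResult",
    "demo_panel_truth",
    "demo_sequences",
    "correlate_panel",
    "run_pipeline",
]

logger = logging.getLogger("curlikin")


@dataclass(frozen=True)
class CorrelationResult:
    """Panel-level rank correlations of lag time with native-MS observables."""

    rho_lag_vs_dimer: float
    rho_lag_vs_norm_ccs: float
    n: int
    method: str = "spearman"


@dataclass
class AnalysisConfig:
    """Configuration for a pipeline run (all-synthetic by default).

    ``panel`` may list per-homolog truth dicts (label, y0, a, x0, k,
    dimer_fraction, dimer_ccs, mass); when omitted the bundled demo panel
    is used.  ``fasta`` optionally points at real sequences for the motif
    stage; otherwise synthetic demo sequences are scanned.
    """

    seed: int = 0
    out_dir: str = "curlikin_out"
    noise_kind: str = "multiplicative-gaussian"
    noise_sd: float = 0.02
    tht_replicates: int = 3
    mz_tolerance: float = 0.5
    true_kd_uM: float = 416.0
    conc_pairs: tuple = ((10.0, 10.0), (20.0, 20.0))
    titration_replicates: int = 3
    response: dict = field(default_factory=lambda: {"p1": 2.0, "p2": 1.0})
    correlation_method: str = "spearman"
    fasta: str | None = None
    panel: list | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if cfg.fasta is not None and not Path(cfg.fasta).exists():
            raise FileNotFoundError(f"config field 'fasta': no such file {cfg.fasta!r}")
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        d["conc_pairs"] = [list(p) for p in self.conc_pairs]
        return yaml.safe_dump(d, sort_keys=False)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Report bundle: per-homolog panel table, correlations, Kd, motifs, paths."""

    panel: pd.DataFrame
    correlations: CorrelationResult
    kd: KdEstimate
    motifs: pd.DataFrame
    identity: pd.DataFrame
    paths: dict
    config_hash: str
    seed: int


def demo_panel_truth() -> list[HomologTruth]:
    """Five synthetic homologs spanning fast to slow aggregation.

    Lag times (0.5, 1.5, 2.5, 5.5, 10 h) span the range observed across
    curli-subunit homologs; dimer fraction rises and normalized dimer CCS
    falls monotonically with lag, the configuration the correlation stage
    is designed to detect.
    """
    rows = [
        # label, x0, k, dimer fraction, normalized dimer CCS (A^2/Da), monomer mass
        ("homolog-A", 1.1, 0.3, 0.02, 0.115, 13100.0),
        ("homolog-B", 2.3, 0.4, 0.04, 0.110, 13400.0),
        ("homolog-C", 3.5, 0.5, 0.08, 0.105, 12900.0),
        ("homolog-D", 7.1, 0.8, 0.12, 0.100, 13150.0),
        ("homolog-E", 12.0, 1.0, 0.16, 0.095, 13600.0),
    ]
    return [
        HomologTruth(
            label=label,
            sigmoid=SigmoidParams(y0=0.0, a=1.0, x0=x0, k=k),
            dimer_fraction=f,
            dimer_ccs=norm * 2.0 * mass,
            mass=mass,
        )
        for label, x0, k, f, norm, mass in rows
    ]


_REPEAT = "QFGSDNSALNSQ"  # literal curli consensus: Q-X4-N-X5-Q
_LINKERS = ["GSG", "AGT", "SGD", "TAG"]


def demo_sequences(n: int = 5) -> list[ProteinSequence]:
    """Synthetic curli-like sequences, five repeat units each.

    Purely constructed stand-ins for real curli subunit sequences (which
    are not machine-readable here); each carries five copies of the
    consensus so the motif scanner has known ground truth.
    """
    seqs = []
    for i in range(n):
        parts = ["M" + "AEVK"[i % 4]]
        for j in range(4):
            parts.append(_REPEAT)
            parts.append(_LINKERS[(i + j) % len(_LINKERS)])
        parts.append(_REPEAT)
        seqs.append(ProteinSequence(id=f"synthetic-curli-{i + 1}", residues="".join(parts)))
    return seqs


def correlate_panel(
    panel: pd.DataFrame, method: str = "spearman"
) -> CorrelationResult:
    """Correlate lag time with % dimer and with normalized CCS across homologs.

    Requires ``lag_h``, ``percent_dimer`` and ``normalized_ccs`` columns
    and at least 3 complete homologs.  Spearman by default (robust at the
    small n typical of homolog panels); Pearson available.  No p-values
    are reported: n is tiny.
    """
    cols = ["lag_h", "percent_dimer", "normalized_ccs"]
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel table missing observables: {missing}")
    complete = panel.dropna(subset=cols)
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >= 3 homologs with complete observables, got {n}")
    if method == "spearman":
        r1 = stats.spearmanr(complete["lag_h"], complete["percent_dimer"]).statistic
        r2 = stats.spearmanr(complete["lag_h"], complete["normalized_ccs"]).statistic
    elif method == "pearson":
        r1 = stats.pearsonr(complete["lag_h"], complete["percent_dimer"]).statistic
        r2 = stats.pearsonr(complete["lag_h"], complete["normalized_ccs"]).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        rho_lag_vs_dimer=float(r1),
        rho_lag_vs_norm_ccs=float(r2),
        n=n,
        method=method,
    )


def _panel_truth_from_config(config: AnalysisConfig) -> list[HomologTruth]:
    if config.panel is None:
        return demo_panel_truth()
    return [
        HomologTruth(
            label=h["label"],
            sigmoid=SigmoidParams(
                y0=h.get("y0", 0.0), a=h.get("a", 1.0), x0=h["x0"], k=h["k"]
            ),
            dimer_fraction=h["dimer_fraction"],
            dimer_ccs=h["dimer_ccs"],
            mass=h["mass"],
        )
        for h in config.panel
    ]


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run every stage on a (synthetic) homolog panel and write the report.

    Stage order: simulate -> kinetics -> spectra -> binding -> mobility ->
    motifs -> correlate.  Any stage failure aborts with the stage name in
    the exception; partial outputs written so far are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    logger.info(
        "pipeline start: seed=%d config=%s", config.seed, config.config_hash
    )
    (out / "config.yaml").write_text(config.to_yaml())
    paths: dict[str, Path] = {"config": out / "config.yaml", "log": out / "run.log"}

    stage = "simulate"
    try:
        noise = NoiseModel(config.noise_kind, config.noise_sd, config.seed)
        panel_truth = _panel_truth_from_config(config)
        panel_data = generate_homolog_panel(
            panel_truth, noise=noise, tht_replicates=config.tht_replicates
        )
        logger.info("simulated panel of %d homologs", len(panel_truth))

        stage = "kinetics"
        kin_rows = []
        for t in panel_truth:
            fits = [fit_sigmoid(tr) for tr in panel_data.tht[t.label]]
            s = summarize_replicates(fits)
            kin_rows.append(
                {
                    "label": t.label,
                    "lag_h": s.mean_lag,
                    "sem_lag_h": s.sem_lag,
                    "k_h": s.mean_k,
                    "sem_k_h": s.sem_k,
                    "n_replicates": s.n,
                    "true_lag_h": t.sigmoid.lag_time,
                }
            )
        kin_df = pd.DataFrame(kin_rows)
        kin_df.to_csv(out / "kinetics_fits.csv", index=False)
        paths["kinetics"] = out / "kinetics_fits.csv"
        logger.info("kinetics: fitted %d homologs", len(kin_df))

        stage = "spectra"
        dim_rows = []
        for t in panel_truth:
            mono, dim = panel_data.species[t.label]
            assignments = assign_peaks(
                panel_data.spectra[t.label],
                [mono, dim],
                panel_data.envelopes[t.label],
                tolerance=config.mz_tolerance,
            )
            q = percent_dimer(assignments, mono.name, dim.name)
            dim_rows.append(
                {
                    "label": t.label,
                    "percent_dimer": q.percent_dimer,
                    "monomer_area": q.monomer_area,
                    "dimer_area": q.dimer_area,
                    "n_assigned": len(assignments),
                    "true_dimer_fraction_pct": 100.0 * t.dimer_fraction,
                }
            )
        dim_df = pd.DataFrame(dim_rows)
        dim_df.to_csv(out / "percent_dimer.csv", index=False)
        paths["spectra"] = out / "percent_dimer.csv"
        logger.info("spectra: quantified dimer share for %d homologs", len(dim_df))

        stage = "binding"
        titration = generate_titration_dataset(
            true_kd=config.true_kd_uM,
            conc_pairs=tuple(tuple(p) for p in config.conc_pairs),
            response=config.response,
            noise=NoiseModel(config.noise_kind, config.noise_sd, config.seed + 1),
            replicates=config.titration_replicates,
        )
        # response calibration from known-concentration standards (5-40 uM)
        cal_rng = np.random.default_rng(config.seed + 2)
        cal_conc = np.array([5.0, 10.0, 20.0, 40.0])
        cal_noise = NoiseModel(config.noise_kind, config.noise_sd, config.seed + 2)
        calib_p1 = fit_response_calibration(
            list(
                zip(
                    cal_conc,
                    cal_noise.apply(titration.response["p1"] * cal_conc, rng=cal_rng),
                )
            )
        )
        calib_p2 = fit_response_calibration(
            list(
                zip(
                    cal_conc,
                    cal_noise.apply(titration.response["p2"] * cal_conc, rng=cal_rng),
                )
            )
        )
        reps = []
        for row in titration.table.itertuples():
            reps.append(
                TitrationReplicate(
                    p1_0=row.p1_0_uM,
                    p2_0=row.p2_0_uM,
                    ab_p1=calib_p1.to_concentration(row.ab_p1),
                    ab_complex=calib_p1.to_concentration(row.ab_complex),
                )
            )
        kd = estimate_kd(reps)
        kd_df = pd.DataFrame(
            {
                "replicate": range(kd.n),
                "kd_uM": kd.values,
            }
        )
        kd_df.to_csv(out / "kd_replicates.csv", index=False)
        (out / "kd_report.txt").write_text(
            "Kd inference (1:1 complex, calibrated abundance ratios)\n"
            f"  n replicates : {kd.n}\n"
            f"  mean Kd      : {kd.mean:.1f} uM\n"
            f"  sample SD    : {kd.sd:.1f} uM\n"
            f"  true Kd      : {titration.true_kd:.1f} uM (synthetic ground truth)\n"
            f"  calibration  : P1 R^2={calib_p1.r_squared:.4f}, "
            f"P2 R^2={calib_p2.r_squared:.4f}\n"
        )
        paths["kd"] = out / "kd_replicates.csv"
        logger.info("binding: mean Kd %.1f uM (n=%d)", kd.mean, kd.n)

        stage = "mobility"
        ccs_cal = fit_ccs_calibration(panel_data.mobility.calibrants)
        ccs_rows = []
        for t in panel_truth:
            dim_name = f"{t.label}-dimer"
            sub = panel_data.mobility.analytes.query("species == @dim_name")
            per_charge = [
                ccs_from_drift(r.drift_ms, int(r.charge), r.mass_da, ccs_cal)
                for r in sub.itertuples()
            ]
            mean_ccs, unc = ccs_uncertainty(per_charge)
            ccs_rows.append(
                {
                    "label": t.label,
                    "species": dim_name,
                    "ccs_A2": mean_ccs,
                    "uncertainty_A2": unc,
                    "normalized_ccs": normalized_ccs(mean_ccs, 2.0 * t.mass),
                    "n_charges": len(per_charge),
                    "true_ccs_A2": t.dimer_ccs,
                }
            )
        ccs_df = pd.DataFrame(ccs_rows)
        ccs_df.to_csv(out / "ccs.csv", index=False)
        paths["mobility"] = out / "ccs.csv"
        logger.info(
            "mobility: calibration R^2 = %.6f, %d species", ccs_cal.r_squared, len(ccs_df)
        )

        stage = "motifs"
        seqs = (
            cio.read_fasta(config.fasta) if config.fasta else demo_sequences()
        )
        motif_rows = []
        for sq in seqs:
            for m in find_curli_repeats(sq):
                motif_rows.append(
                    {
                        "seq_id": sq.id,
                        "start": m.start,
                        "end": m.end,
                        "subsequence": m.subsequence,
                    }
                )
        motif_df = pd.DataFrame(
            motif_rows, columns=["seq_id", "start", "end", "subsequence"]
        )
        motif_df.to_csv(out / "motifs.csv", index=False)
        ident = pd.DataFrame(
            [
                [percent_identity(a, b) for b in seqs]
                for a in seqs
            ],
            index=[s.id for s in seqs],
            columns=[s.id for s in seqs],
        )
        ident.to_csv(out / "identity.csv")
        paths["motifs"] = out / "motifs.csv"
        logger.info("motifs: %d repeat units in %d sequences", len(motif_df), len(seqs))

        stage = "correlate"
        panel_df = kin_df.merge(dim_df, on="label").merge(ccs_df, on="label")
        corr = correlate_panel(panel_df, method=config.correlation_method)
        panel_df.to_csv(out / "panel_summary.csv", index=False)
        paths["panel"] = out / "panel_summary.csv"

        summary = (
            f"curlikin pipeline summary (seed={config.seed}, "
            f"config={config.config_hash})\n\n"
            + panel_df[
                ["label", "lag_h", "percent_dimer", "normalized_ccs"]
            ].to_string(index=False)
            + "\n\n"
            f"Spearman lag vs %dimer        : {corr.rho_lag_vs_dimer:+.3f}\n"
            f"Spearman lag vs normalized CCS: {corr.rho_lag_vs_norm_ccs:+.3f}\n"
            f"n homologs                    : {corr.n}\n\n"
            f"Kd (1:1 complex): {kd.mean:.1f} +/- {kd.sd:.1f} uM (n={kd.n})\n"
        )
        (out / "summary.txt").write_text(summary)
        paths["summary"] = out / "summary.txt"
        logger.info("pipeline complete")
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        panel=panel_df,
        correlations=corr,
        kd=kd,
        motifs=motif_df,
        identity=ident,
        paths=paths,
        config_hash=config.config_hash,
        seed=config.seed,
    )


def _setup_logging(logfile: Path) -> None:
    # stderr + file, idempotent across repeated runs in one process
    logger.setLevel(logging.INFO)
    for h in list(logger.handlers):
        logger.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(sh)
    logger.addHandler(fh)
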