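"""End-to-end orchestration: synthesise → analyse → report.

Each ``run_*`` function takes a (possibly partial) config dict, merges
it over the defaults below, executes the relevant stages, and returns a
:class:`ReportBundle` whose JSON results and tidy CSV tables can be
written to disk.  Reruns with an identical resolved config are
bit-identical: no timestamps enter the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import mechanics, saxs, seqmotif, synthgen, waxd

log = logging.getLogger("silkstruct")

__all__ = [
    "ReportBundle",
    "DEFAULT_STATIC_CONFIG",
    "DEFAULT_DEFORMATION_CONFIG",
    "DEFAULT_SEQUENCE_CONFIG",
    "run_static_analysis",
    "run_deformation_analysis",
    "run_sequence_analysis",
]


def _merge(base, override):
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class ReportBundle:
    """Per-stage JSON-able results, tidy tables, and provenance."""

    results: dict
    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, payload in self.results.items():
            (outdir / f"{name}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True, default=float)
            )
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=float)
        )
        return outdir


def _provenance(config, seed):
    return {"package": "silkstruct", "version": __version__,
            "seed": seed, "resolved_config": config}


# ---------------------------------------------------------------------------
# static structural characterisation
# ---------------------------------------------------------------------------

DEFAULT_STATIC_CONFIG = {
    "lamellar": {"long_period": 38.5, "phase1_fraction": 15.7 / 38.5,
                 "n_orders": 5, "peak_width_sigma": 0.015,
                 "background_level": 0.0, "noise": None},
    "equatorial": {"bundle_thickness": 150.0, "fibril_spacing": 4.7,
                   "instrumental_fwhm": 0.005},
    "waxd": {"crystallinity_true": 0.44, "orientation_fwhm": 20.0,
             "noise": None},
    "analysis": {"z_max": 100.0, "corr_background": "none"},
    "plots": False,
}


def run_static_analysis(config=None, seed=0) -> ReportBundle:
    """Static characterisation: crystallinity, unit cell, long-period
    harmonics, correlation-function decomposition, and bundle thickness,
    on synthetic inputs with recorded ground truth."""
    cfg = _merge(DEFAULT_STATIC_CONFIG, config)
    log.info("static analysis config: %s", cfg)

    lam = synthgen.LamellarModelParams(seed=seed, **cfg["lamellar"])
    meridional = synthgen.generate_saxs_meridional(lam)
    kratky = saxs.kratky_transform(meridional)
    lp = saxs.find_harmonic_peaks(kratky)
    corr = saxs.correlation_function(
        meridional, z_max=cfg["analysis"]["z_max"],
        background=cfg["analysis"]["corr_background"],
    )

    eq = synthgen.generate_saxs_equatorial(seed=seed, **cfg["equatorial"])
    center, fwhm = saxs.fit_equatorial_peak(eq)
    sch = saxs.scherrer_thickness(
        center, fwhm, cfg["equatorial"]["instrumental_fwhm"], eq.wavelength,
    )

    wparams = synthgen.default_waxd_params(seed=seed, **cfg["waxd"])
    profile = synthgen.generate_waxd_profile(wparams)
    cell = synthgen.DEFAULT_CELL
    cres = waxd.fit_crystallinity(profile, cell)
    solved = waxd.solve_unit_cell(
        cell.d_spacing(2, 0, 0), cell.d_spacing(2, 1, 0), cell.d_spacing(0, 0, 2)
    )

    results = {
        "long_period": {
            "lp_1st_nm": lp.lp_1st, "lp_2nd_nm": lp.lp_2nd,
            "lp_3rd_nm": lp.lp_3rd, "ratio_2nd_3rd": lp.ratio_2nd_3rd,
            "peaks_q_nm^-1": [list(p) for p in lp.peak_positions_q],
        },
        "correlation": {
            "invariant_Q": corr.Q, "Lp_nm": corr.Lp, "d_pI_nm": corr.d_pI,
            "d_pI_mean_nm": corr.d_pI_mean,
            "phase2_thickness_nm": corr.phase2_thickness,
            "phase1_fraction": corr.phase1_fraction,
            "phase_labels": corr.phase_labels,
        },
        "scherrer": {"bundle_thickness_nm": sch.d,
                     "beta_rad": sch.beta, "k_factor": sch.k_factor},
        "crystallinity": cres.as_dict(),
        "unit_cell": {"a_angstrom": solved.a, "b_angstrom": solved.b,
                      "c_angstrom": solved.c},
        "ground_truth": {
            "lamellar": meridional.meta["truth"],
            "equatorial": eq.meta["truth"],
            "waxd": profile.meta["truth"],
        },
    }
    summary = pd.DataFrame([
        {"quantity": "crystallinity", "value": cres.Xc, "units": "%"},
        {"quantity": "long_period_1st", "value": lp.lp_1st, "units": "nm"},
        {"quantity": "phase1_mean_thickness", "value": corr.d_pI_mean,
         "units": "nm"},
        {"quantity": "phase2_thickness", "value": corr.phase2_thickness,
         "units": "nm"},
        {"quantity": "bundle_thickness", "value": sch.d, "units": "nm"},
    ])
    bundle = ReportBundle(results=results, tables={"structure_summary": summary},
                          provenance=_provenance(cfg, seed))
    if cfg.get("plots"):
        bundle.results["figures"] = _static_figures(kratky, corr)
    return bundle


def _static_figures(kratky, corr, outdir="figures"):
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover - plotting is optional
        return {"skipped": "matplotlib not available"}
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots()
    ax.plot(kratky.abscissa, kratky.intensity)
    ax.set_xlabel("q (nm$^{-1}$)")
    ax.set_ylabel("q$^2$I(q)")
    fig.savefig(out / "kratky.png", dpi=150)
    plt.close(fig)
    fig, ax = plt.subplots()
    ax.plot(corr.z, corr.K / corr.Q)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("z (nm)")
    ax.set_ylabel("K(z)/Q")
    fig.savefig(out / "correlation.png", dpi=150)
    plt.close(fig)
    return {"kratky": str(out / "kratky.png"),
            "correlation": str(out / "correlation.png")}


# ---------------------------------------------------------------------------
# time-resolved deformation
# ---------------------------------------------------------------------------

DEFAULT_DEFORMATION_CONFIG = {
    "tensile": {"modulus": 12.0, "yield_strain": 0.033,
                "hardening_slope": 5.35, "fracture_strain": 0.22,
                "noise_sd": 0.0},
    "structure": {
        "d002_initial": 3.52, "d002_yield": 3.54, "d002_fracture": 3.57,
        "lp_initial": 37.5, "lp_yield": 38.1, "lp_fracture": 44.7,
        "orientation_initial": 0.90, "orientation_fracture": 0.85,
    },
    "frame_interval": 9.0,        # s (8 s exposure + 1 s readout)
    "gauge_length_mm": 15.0,
    "crosshead_um_s": 10.0,
}


def _synthesize_deformation_experiment(cfg, seed=0):
    """Forward-model a stretching run: tensile log plus per-frame d002,
    orientation, and long periods, all piecewise-linear in bulk strain
    with the configured stage-I/stage-II anchors."""
    t = cfg["tensile"]
    s = cfg["structure"]
    params = synthgen.TensileModelParams(seed=seed, **t)
    rate = cfg["crosshead_um_s"] / 1000.0 / cfg["gauge_length_mm"]  # strain/s
    t_end = params.fracture_strain / rate
    log_t = np.arange(0.0, t_end + 1e-9, 1.0)
    log_strain = np.minimum(log_t * rate, params.fracture_strain)
    sigma_y = params.modulus * params.yield_strain
    log_stress = np.where(
        log_strain <= params.yield_strain,
        params.modulus * log_strain,
        sigma_y + params.hardening_slope * (log_strain - params.yield_strain),
    )
    tensile_log = pd.DataFrame({
        "time": log_t, "strain_percent": log_strain * 100.0,
        "stress_gpa": log_stress,
    })

    frame_t = np.arange(0.0, t_end + 1e-9, cfg["frame_interval"])
    if t_end - frame_t[-1] > 1e-9:  # always capture the fracture frame
        frame_t = np.append(frame_t, t_end)
    strain = np.minimum(frame_t * rate, params.fracture_strain)
    anchors = np.array([0.0, params.yield_strain, params.fracture_strain])
    d002 = np.interp(strain, anchors,
                     [s["d002_initial"], s["d002_yield"], s["d002_fracture"]])
    lp1 = np.interp(strain, anchors,
                    [s["lp_initial"], s["lp_yield"], s["lp_fracture"]])
    orient = np.interp(strain, [0.0, params.fracture_strain],
                       [s["orientation_initial"], s["orientation_fracture"]])
    frames = pd.DataFrame({
        "time": frame_t, "d002": d002, "orientation_index": orient,
        "lp_2nd": lp1 / 2.0, "lp_3rd": lp1 / 3.0, "lp_1st": lp1,
    })
    return frames, tensile_log, params


def run_deformation_analysis(config=None, seed=0) -> ReportBundle:
    """Time-resolved analysis: joined per-frame series and a stage table
    (stage I / stage II / total) in the layout of the deformation
    summary."""
    cfg = _merge(DEFAULT_DEFORMATION_CONFIG, config)
    log.info("deformation analysis config: %s", cfg)
    frames, tensile_log, params = _synthesize_deformation_experiment(cfg, seed)
    series = saxs.assemble_deformation_series(
        frames, tensile_log, frame_interval=cfg["frame_interval"])

    f = series.frames
    gauge = cfg["gauge_length_mm"]

    def _row_at(strain_pct):
        idx = (f["bulk_strain"] - strain_pct).abs().idxmin()
        return f.loc[idx]

    y_pct = series.yield_strain_percent
    frac_pct = series.fracture_strain_percent
    bounds = [0.0] + ([y_pct] if y_pct is not None else []) + [frac_pct]
    rows = []
    labels = (["I", "II"] if y_pct is not None else ["I"])
    for label, (a, b) in zip(labels, zip(bounds, bounds[1:])):
        ra, rb = _row_at(a), _row_at(b)
        rows.append(_stage_row(label, ra, rb, gauge))
    rows.append(_stage_row("total", _row_at(0.0), _row_at(frac_pct), gauge))
    stage_table = pd.DataFrame(rows)

    results = {
        "stages": {
            "yield_strain_percent": y_pct,
            "fracture_strain_percent": frac_pct,
            "boundaries_percent": series.stages,
        },
        "ratio_2nd_3rd": {
            "mean": float(f["lp_ratio_2nd_3rd"].mean()),
            "std": float(f["lp_ratio_2nd_3rd"].std(ddof=0)),
        },
        "ground_truth": {
            "yield_strain": params.yield_strain,
            "fracture_strain": params.fracture_strain,
            "modulus_gpa": params.modulus,
        },
    }
    return ReportBundle(
        results=results,
        tables={"deformation_series": f, "stage_table": stage_table},
        provenance=_provenance(cfg, seed),
    )


def _stage_row(label, ra, rb, gauge):
    return {
        "stage": label,
        "sample_length_mm": f"{gauge * (1 + ra['bulk_strain'] / 100):.1f} -> "
                            f"{gauge * (1 + rb['bulk_strain'] / 100):.1f}",
        "bulk_strain_percent": rb["bulk_strain"] - ra["bulk_strain"],
        "d002_angstrom": f"{ra['d002']:.2f} -> {rb['d002']:.2f}",
        "crystal_strain_percent": rb["crystal_strain"] - ra["crystal_strain"],
        "lp_1st_nm": f"{ra['lp_1st']:.1f} -> {rb['lp_1st']:.1f}",
        "lp_strain_percent": rb["lp_strain"] - ra["lp_strain"],
    }


# ---------------------------------------------------------------------------
# sequence → structure
# ---------------------------------------------------------------------------

DEFAULT_SEQUENCE_CONFIG = {
    "generate": {"n_motifs": 5, "pab_length": 22,
                 "npab_pre_insert_length": 45, "insert_length": 6,
                 "npab_post_insert_length": 87},
    "fasta": None,              # path to a FASTA file; overrides "generate"
    "min_run": 10,
    "residue_rise": seqmotif.BETA_RESIDUE_RISE_NM,
    "amorphous_phase_thickness": 15.7,
    "phase2_thickness_reference": 22.8,
}


def run_sequence_analysis(config=None, seed=0) -> ReportBundle:
    """Motif census of a (generated or supplied) fibroin-like sequence
    plus the residue-count → phase-length mapping."""
    cfg = _merge(DEFAULT_SEQUENCE_CONFIG, config)
    log.info("sequence analysis config: %s", cfg)
    if cfg["fasta"]:
        from Bio import SeqIO

        records = list(SeqIO.parse(cfg["fasta"], "fasta"))
        if not records:
            raise ValueError(f"no sequences in {cfg['fasta']}")
        sequence = str(records[0].seq)
        truth = None
    else:
        params = synthgen.SequenceModelParams(seed=seed, **cfg["generate"])
        records, truth = synthgen.generate_sequences(params)
        sequence = str(records[0].seq)

    blocks = seqmotif.find_polyalanine_blocks(sequence, min_run=cfg["min_run"])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        motifs = seqmotif.segment_tandem_motifs(sequence, blocks)

    motif_rows = []
    for i, m in enumerate(motifs, start=1):
        chem = seqmotif.classify_npab_chemistry(m, sequence)
        motif_rows.append({
            "motif": i,
            "pab_start": m.pab_span[0], "pab_end": m.pab_span[1],
            "npab_start": m.npab_span[0], "npab_end": m.npab_span[1],
            "insert_start": m.insert_span[0] if m.insert_span else None,
            "insert_end": m.insert_span[1] if m.insert_span else None,
            "motif_length": m.motif_length,
            "gx_fraction": chem["gx_fraction"],
            "ggx_fraction": chem["ggx_fraction"],
        })
    table = pd.DataFrame(motif_rows)

    results = {"n_polyalanine_blocks": len(blocks),
               "blocks": [list(b) for b in blocks],
               "n_motifs": len(motifs)}
    if motifs:
        m0 = motifs[0]
        pab_n = m0.pab_span[1] - m0.pab_span[0] + 1
        if m0.insert_span:
            crystal_npab = m0.insert_span[0] - m0.npab_span[0]
            amorphous_n = m0.npab_span[1] - m0.insert_span[0] + 1
        else:
            crystal_npab = m0.npab_span[1] - m0.npab_span[0] + 1
            amorphous_n = 0
        smap = seqmotif.map_to_phase_lengths(
            pab_n, crystal_npab, amorphous_n,
            residue_rise=cfg["residue_rise"],
            amorphous_phase_thickness=cfg["amorphous_phase_thickness"],
        )
        results["phase_map"] = {
            "n_crystal_residues": smap.n_crystal_residues,
            "n_amorphous_residues": smap.n_amorphous_residues,
            "crystal_length_nm": smap.crystal_length,
            "amorphous_contour_nm": smap.amorphous_contour,
            "amorphous_shrinkage_percent": smap.amorphous_shrinkage,
            "predicted_long_period_nm": smap.predicted_long_period,
            "phase2_thickness_reference_nm": cfg["phase2_thickness_reference"],
            "crystal_vs_phase2_diff_nm":
                smap.crystal_length - cfg["phase2_thickness_reference"],
        }
    if truth is not None:
        results["ground_truth"] = truth
    return ReportBundle(results=results, tables={"motifs": table},
                        provenance=_provenance(cfg, seed))
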