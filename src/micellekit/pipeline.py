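"""End-to-end report assembly.

``run_pipeline`` drives the full analysis from a flat config dict: per-
technique CMC fits with a consensus check, the Gibbs surface analysis, a
SAXS model fit, the forward-scattering association-number chain and the
MD aggregation propensity.  Stages run independently: a failure in one is
recorded in its block and the rest continue.  Stages whose inputs are not
configured are marked absent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__, absolute_intensity, gibbs, io, md_postproc
from . import saxs_model as sm
from . import titration as ti

log = logging.getLogger("micellekit")

__all__ = ["run_pipeline", "render_text"]


def _stage(report: dict, name: str):
    """Decorator-less stage guard: returns a context manager recording errors."""

    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s failed: %s", name, exc)
                report[name] = {"error": f"{exc_type.__name__}: {exc}"}
                return True
            return False

    return _Ctx()


def run_pipeline(config: dict, seed: int | None = None) -> dict:
    """Run every configured analysis stage and assemble a report dict.

    Config keys (all optional except where a stage needs them):

    * ``molecule``, ``M_mol``, ``n_carbons``, ``temperature``
    * ``titration``: mapping technique -> CSV path
    * ``gibbs``: ``{"slope": ..., "log_base": "ln", "radius": ...}``
      (slope in N/m per unit log c; falls back to the fitted surface-tension
      pre-CMC slope when omitted and a surface-tension file is present)
    * ``saxs``: ``{"file": ..., "init": {...}, "fixed": [...]}``
    * ``forward``: ``{"I0": ..., "conc_wt": ..., "v_p": ...}``
      (I0 falls back to the fitted SAXS forward intensity)
    * ``ap``: ``{"file": ..., "init_window": [lo, hi], "final_window": [lo, hi]}``
    * ``bootstrap``: ``{"n_boot": 1000}``
    """
    report: dict = {
        "version": __version__,
        "seed": seed,
        "molecule": config.get("molecule"),
        "config": {k: v for k, v in config.items() if not isinstance(v, dict)},
    }
    T = float(config.get("temperature", 293.0))

    # ---- CMC per technique -------------------------------------------
    estimates = []
    tcfg = config.get("titration")
    if tcfg:
        block = {}
        n_boot = int(config.get("bootstrap", {}).get("n_boot", 1000))
        for technique, path in tcfg.items():
            with _stage(block, technique):
                series = io.read_titration_csv(path, technique)
                est = ti.fit_two_segment(series)
                if est.detected and seed is not None:
                    est.ci95 = ti.bootstrap_breakpoint_ci(
                        series, n_boot=n_boot, seed=seed
                    )
                estimates.append(est)
                block[technique] = est.to_dict()
        with _stage(block, "consensus"):
            block["consensus"] = ti.consensus_cmc(estimates)
        report["cmc"] = block
    else:
        report["cmc"] = {"absent": True}

    # ---- Gibbs surface analysis --------------------------------------
    gcfg = config.get("gibbs")
    if gcfg is not None:
        with _stage(report, "gibbs"):
            slope = gcfg.get("slope")
            if slope is None:
                st = next(
                    (e for e in estimates if e.technique == "surface_tension"), None
                )
                if st is None:
                    raise ValueError("no slope given and no surface_tension fit")
                # fitted slope is per log10(c); convert to per ln c
                slope = st.slopes[0] / 2.302585092994046
                # response in mN/m -> N/m
                slope *= 1e-3
            analysis, assoc = gibbs.gibbs_pipeline(
                slope=float(slope),
                T=float(gcfg.get("temperature", T)),
                radius=gcfg.get("radius"),
                log_base=gcfg.get("log_base", "ln"),
            )
            blk = {
                "slope_per_ln_c": analysis.slope,
                "temperature": analysis.temperature,
                "surface_excess": analysis.surface_excess,
                "area_per_molecule": analysis.area_per_molecule,
                "surface_inactive": analysis.surface_inactive,
            }
            if assoc is not None:
                blk.update(
                    {"radius": assoc.radius, "a_mic": assoc.a_mic, "p_surface": assoc.p_surface}
                )
            report["gibbs"] = blk
    else:
        report["gibbs"] = {"absent": True}

    # ---- SAXS fit -----------------------------------------------------
    saxs_fit = None
    scfg = config.get("saxs")
    if scfg is not None:
        with _stage(report, "saxs"):
            curve = io.read_saxs_dat(scfg["file"])
            init = sm.MicelleModelParams(**scfg.get("init", {}))
            saxs_fit = sm.fit_saxs(
                curve,
                init,
                fixed=tuple(scfg.get("fixed", ())),
                multi_start=int(scfg.get("multi_start", 1)),
                seed=seed,
            )
            report["saxs"] = {
                "params": saxs_fit.params.to_dict(),
                "chi2_red": saxs_fit.chi2_red,
                "stderr": saxs_fit.stderr,
                "success": saxs_fit.success,
                "I0": sm.forward_intensity(saxs_fit.params),
            }
    else:
        report["saxs"] = {"absent": True}

    # ---- forward scattering -> M_mic, p ------------------------------
    fcfg = config.get("forward")
    if fcfg is not None:
        with _stage(report, "forward"):
            I0 = fcfg.get("I0")
            if I0 is None:
                if saxs_fit is None:
                    raise ValueError("no I0 given and no SAXS fit available")
                I0 = sm.forward_intensity(saxs_fit.params)
            # wt% -> g/cm^3 at solution density 1.00 g/cm^3
            c = fcfg.get("c_mic", fcfg.get("conc_wt", 1.0) * 0.01)
            contrast = absolute_intensity.ContrastModel.from_tail(
                n_carbons=int(config.get("n_carbons", 15)),
                v_p=float(fcfg.get("v_p", 1.15)),
            )
            res = absolute_intensity.forward_scatter_pipeline(
                I0=float(I0),
                c_mic=float(c),
                M_mol=float(config["M_mol"]),
                contrast=contrast,
            )
            report["forward"] = {
                "I0": res.I0,
                "c_mic": res.c_mic,
                "v_l": contrast.v_l,
                "rho_l": contrast.rho_l,
                "delta_rho": contrast.delta_rho,
                "M_mic": res.M_mic,
                "M_mol": res.M_mol,
                "p": res.p,
            }
    else:
        report["forward"] = {"absent": True}

    # ---- aggregation propensity --------------------------------------
    acfg = config.get("ap")
    if acfg is not None:
        with _stage(report, "ap"):
            trace = io.read_xvg(acfg["file"], observable=acfg.get("observable", "sasa"))
            res = md_postproc.aggregation_propensity(
                trace,
                init_window=tuple(acfg["init_window"]) if "init_window" in acfg else None,
                final_window=tuple(acfg["final_window"]) if "final_window" in acfg else None,
            )
            report["ap"] = res.to_dict()
    else:
        report["ap"] = {"absent": True}

    return report


def render_text(report: dict) -> str:
    """Human-readable rendering of a pipeline report."""
    lines = [f"micellekit report (v{report.get('version')})"]
    mol = report.get("molecule")
    if mol:
        lines.append(f"molecule: {mol}")
    cmc = report.get("cmc", {})
    if not cmc.get("absent"):
        lines.append("-- CMC --")
        for k, v in cmc.items():
            if k == "consensus":
                lines.append(
                    f"  consensus: agreement={v.get('agreement')} "
                    f"max_ratio={v.get('max_ratio', float('nan')):.3g}"
                    if "error" not in v
                    else f"  consensus: {v['error']}"
                )
            elif isinstance(v, dict) and "cmc" in v:
                ci = v.get("ci95")
                ci_s = f" CI95=[{ci[0]:.4g}, {ci[1]:.4g}]" if ci else ""
                lines.append(
                    f"  {k}: CMC={v['cmc']:.4g} {v.get('conc_unit', '')}"
                    f" detected={v['detected']}{ci_s}"
                )
            elif isinstance(v, dict) and "error" in v:
                lines.append(f"  {k}: ERROR {v['error']}")
    for name in ("gibbs", "forward", "saxs", "ap"):
        blk = report.get(name, {})
        if blk.get("absent"):
            lines.append(f"-- {name} -- absent")
            continue
        lines.append(f"-- {name} --")
        if "error" in blk:
            lines.append(f"  ERROR {blk['error']}")
            continue
        for k, v in blk.items():
            if isinstance(v, float):
                lines.append(f"  {k} = {v:.6g}")
            elif not isinstance(v, (dict, list)):
                lines.append(f"  {k} = {v}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str) + "\n")
    (out / "report.txt").write_text(render_text(report))
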