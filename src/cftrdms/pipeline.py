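"""End-to-end synthetic pipeline driver: simulate -> score -> respond ->
interactome -> kinetics, with a checksum manifest for reproducibility.

Every stage derives its randomness from the single config seed through
named sub-seeds, so re-running an identical config reproduces every output
file bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import interactome as im
from . import io as cio
from . import kinetics as kin
from . import response as resp
from . import scoring
from . import simulate as sim
from .config import RunConfig
from .variants import DomainMap

log = logging.getLogger("cftrdms")

CONDITIONS = [
    ("parental", "vehicle"),
    ("CANX_KO", "vehicle"),
    ("parental", "VX445"),
    ("CANX_KO", "VX445"),
]


def _sub_seed(seed: int, *labels: str) -> int:
    h = hashlib.sha256(("|".join(str(x) for x in labels) + f"|{seed}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    state: dict = {}

    for stage in ("simulate", "score", "respond", "interactome", "kinetics"):
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            files = _STAGES[stage](config, outdir, state)
        except Exception:
            log.exception("stage %s failed", stage)
            raise
        manifest["stages"][stage] = sorted(str(f.relative_to(outdir)) for f in files)
        for f in files:
            manifest["files"][str(f.relative_to(outdir))] = _sha256(f)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    sec = config.sort_seq
    lib = sim.make_variant_library(sec.n_variants, seed=_sub_seed(config.seed, "library"))
    # corrector responsiveness concentrated in the lowest-expressing third
    order = lib.sort_values("true_mean_log10").variant_id
    responders = set(order.head(max(1, sec.n_variants // 3)))
    cfg = sim.SortSeqSimConfig(
        n_variants=sec.n_variants,
        cells_per_pool=sec.cells_per_pool,
        reads_per_fraction=sec.reads_per_fraction,
        seq_error_rate=sec.seq_error_rate,
        ko_attenuation=sec.ko_attenuation,
        corrector_fold_effects={v: sec.corrector_fold for v in responders},
        seed=_sub_seed(config.seed, "sort_seq"),
    )
    files: list[Path] = []
    wl = scoring.UmiWhitelist(dict(zip(lib["umi"], lib["variant_id"])))
    wl_path = outdir / "whitelist.tsv"
    cio.write_whitelist(wl, wl_path)
    files.append(wl_path)
    lib_path = outdir / "library_truth.tsv"
    cio.write_table(lib, lib_path, index=False)
    files.append(lib_path)

    tables: dict = {}
    for line, trt in CONDITIONS:
        for r in range(1, sec.n_replicates + 1):
            rep = f"rep{r}"
            res = sim.simulate_sort_seq(lib, cfg, cell_line=line, treatment=trt,
                                        replicate_id=rep)
            tag = f"{line}_{trt}_{rep}"
            cpath = outdir / f"counts_{tag}.tsv"
            cio.write_count_table(res.table, cpath)
            fpath = outdir / f"fraction_means_{tag}.tsv"
            cio.write_fraction_means(res.table.fraction_means, fpath)
            files += [cpath, fpath]
            tables[(line, trt, rep)] = res.table
    state["tables"] = tables
    state["library"] = lib
    state["sim_config"] = cfg
    return files


def _stage_score(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    files: list[Path] = []
    if "tables" not in state and config.counts_path:
        means = cio.read_fraction_means(config.fraction_means_path)
        state["tables"] = {
            ("parental", "vehicle", "rep1"): cio.read_count_table(config.counts_path, means)
        }
    if "tables" not in state:
        raise RuntimeError("score stage needs simulated tables or counts_path")
    pme: dict = {}
    rejected: dict = {}
    for (line, trt), _ in {(k[0], k[1]): None for k in state["tables"]}.items():
        reps = [
            scoring.score_replicate(
                tbl,
                seed=_sub_seed(config.seed, "score", line, trt, rep),
                variation_threshold=config.thresholds.variation,
            )
            for (l2, t2, rep), tbl in sorted(state["tables"].items())
            if (l2, t2) == (line, trt)
        ]
        prof = scoring.aggregate_pme(reps)
        pme[(line, trt)] = prof["pme"]
        rejected[(line, trt)] = pd.concat(
            [df.loc[~df["qc_pass"], ["variation"]].assign(replicate=df["replicate_id"]) for df in reps]
        )
        path = outdir / f"pme_{line}_{trt}.tsv"
        cio.write_pme(prof, path, cell_line=line, treatment=trt)
        files.append(path)
    state["pme"] = pme
    state["rejected"] = rejected
    return files


def _stage_respond(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    if "pme" not in state:
        raise RuntimeError("respond stage needs PME profiles from the score stage")
    pme = state["pme"]
    files: list[Path] = []
    table = resp.build_response_table(pme, drug="VX445", floor=config.thresholds.ratio_floor)
    rpath = outdir / "response.tsv"
    cio.write_table(table, rpath)
    files.append(rpath)

    trend = resp.fit_library_trend(pme[("parental", "vehicle")], pme[("CANX_KO", "vehicle")])
    dmap = DomainMap()
    dpme = table["delta_pme"].dropna()
    rows = [
        {
            "metric": "ko_vs_parental_slope",
            "value": trend.slope,
            "detail": f"r2={trend.pearson_r2:.4f};n={trend.n_used}",
        }
    ]
    try:
        dt = resp.domain_compare(dpme, dmap, "NBD1", "NBD2")
        rows.append({"metric": "mw_NBD1_vs_NBD2_p", "value": dt.p,
                     "detail": f"U={dt.u};n={dt.n_a},{dt.n_b}"})
    except ValueError as exc:
        rows.append({"metric": "mw_NBD1_vs_NBD2_p", "value": float("nan"), "detail": str(exc)})
    spath = outdir / "response_stats.tsv"
    cio.write_table(pd.DataFrame(rows), spath, index=False)
    files.append(spath)
    state["response"] = table
    state["trend"] = trend
    return files


def _stage_interactome(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    sec = config.interactome
    cfg = sim.InteractomeSimConfig(
        n_proteins=sec.n_proteins,
        n_true_interactors=sec.n_true_interactors,
        background_sigma=sec.background_sigma,
        effect_sizes=tuple([sec.effect_size] * sec.n_true_interactors),
        n_replicates=sec.n_replicates,
        both_cell_lines=True,
        ko_shift=0.8,
        seed=_sub_seed(config.seed, "interactome"),
    )
    abundance, design, truth = sim.simulate_tmt_interactome(cfg)
    norm = im.normalize_abundances(abundance, design)
    pass_sets: dict[str, set[str]] = {}
    calls_frames = []
    sigma_rows = []
    for line in ("parental", "CANX_KO"):
        fc = im.log2fc_vs_mock(norm, design, cell_line=line)
        background = fc["mean_log2fc"].dropna()
        fit = im.estimate_sigma(background)
        calls = im.curved_filter(
            fc, sigma=fit.sigma, c=config.thresholds.curve_c,
            sigma_multiplier=config.thresholds.sigma_multiplier,
            literal_p=sec.literal_p,
        )
        calls = calls.drop(index=im.BAIT_PROTEIN, errors="ignore")
        calls["cell_line"] = line
        calls_frames.append(calls)
        pass_sets[line] = set(calls.index[calls["passes"]])
        sigma_rows.append({"cell_line": line, "sigma": fit.sigma, "mu": fit.mu,
                           "n_bins": fit.n_bins, "robust_sd": fit.robust_sd})
    files: list[Path] = []
    cpath = outdir / "interactor_calls.tsv"
    cio.write_table(pd.concat(calls_frames), cpath)
    files.append(cpath)
    spath = outdir / "sigma_fits.tsv"
    cio.write_table(pd.DataFrame(sigma_rows), spath, index=False)
    files.append(spath)

    master = im.master_interactor_list(pass_sets)
    mpath = outdir / "master_list.tsv"
    cio.write_table(master, mpath)
    files.append(mpath)

    deltas = im.grouped_delta(norm, design, master.index)
    dpath = outdir / "grouped_deltas.tsv"
    cio.write_table(deltas, dpath)
    files.append(dpath)

    # synthetic pathway classes: true interactors cycle through classes,
    # background falls in 'other'
    classes = [c for c in im.PATHWAY_CLASSES if c != "other"]
    pathway = pd.Series("other", index=truth["protein_id"], name="pathway")
    spiked = truth.loc[truth["is_interactor"], "protein_id"].tolist()
    for i, p in enumerate(spiked):
        pathway[p] = classes[i % len(classes)]
    tests = im.pathway_zero_tests(deltas["delta_log2"], pathway)
    tpath = outdir / "pathway_tests.tsv"
    cio.write_table(tests, tpath)
    files.append(tpath)
    state["interactome"] = {"calls": pd.concat(calls_frames), "master": master,
                            "deltas": deltas, "truth": truth}
    return files


def _stage_kinetics(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    sec = config.kinetics
    rows = []
    for cond, scale in (("WT", 1.0), ("F508del", 0.15)):
        traces = sim.simulate_quench_traces(
            k1=sec.k1 * scale, y0=sec.y0, A1=sec.A1,
            noise_sd=sec.noise_sd * sec.A1, n_cells=sec.n_cells, t_max=sec.t_max,
            seed=_sub_seed(config.seed, "quench", cond), n_replicates=sec.n_replicates,
        )
        fit = kin.fit_quench_global(traces, y0_fixed=sec.y0)
        rows.append({"condition": cond, "k1": fit.k1, "A1": fit.A1, "y0": fit.y0,
                     "t_half": fit.t_half, "rss": fit.rss, "n_obs": fit.n_obs})
    files: list[Path] = []
    fpath = outdir / "quench_fits.tsv"
    cio.write_table(pd.DataFrame(rows), fpath, index=False)
    files.append(fpath)

    # synthetic short-circuit-current trace: forskolin step to a plateau
    rng = np.random.default_rng(_sub_seed(config.seed, "isc"))
    t = np.arange(0.0, 1800.0, 2.0)
    level = 10.0
    y = np.where(t < 600, 0.0, level * (1 - np.exp(-(t - 600) / 30.0)))
    y = y + rng.normal(0, 0.005 * level, len(t))
    trace = pd.DataFrame({"time": t, "current": y})
    res = kin.delta_isc(trace, {"forskolin": 600.0}, "forskolin")
    pct = kin.percent_wt_activity(0.024 * res.delta_i, res.delta_i)
    ipath = outdir / "isc.tsv"
    cio.write_table(
        pd.DataFrame(
            [{"event": "forskolin", "delta_isc": res.delta_i, "baseline": res.baseline,
              "plateau": res.plateau, "percent_wt_example": pct}]
        ),
        ipath, index=False,
    )
    files.append(ipath)
    state["kinetics"] = rows
    return files


_STAGES = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "respond": _stage_respond,
    "interactome": _stage_interactome,
    "kinetics": _stage_kinetics,
}


def write_report(outdir) -> Path:
    """Summarise a completed run into a stable, machine-parseable report."""
    outdir = Path(outdir)
    mpath = outdir / "manifest.json"
    lines = ["# cftrdms run report"]
    if not mpath.exists():
        lines.append("stages_completed: 0")
        rpath = outdir / "report.txt"
        rpath.write_text("\n".join(lines) + "\n")
        return rpath
    manifest = json.loads(mpath.read_text())
    lines.append(f"seed: {manifest['seed']}")
    lines.append(f"stages_completed: {len(manifest['stages'])}")
    for stage, files in sorted(manifest["stages"].items()):
        lines.append(f"## stage {stage}")
        lines.append(f"files: {len(files)}")
        for f in files:
            df = pd.read_csv(outdir / f, sep="\t")
            lines.append(f"  {f}: rows={len(df)}")
    for name in ("pme_parental_vehicle.tsv",):
        p = outdir / name
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            n_fail = int((~df["qc_pass"]).sum()) if "qc_pass" in df else 0
            lines.append(f"variants_scored: {int(df['qc_pass'].sum())}")
            lines.append(f"variants_rejected: {n_fail}")
    rpath = outdir / "report.txt"
    rpath.write_text("\n".join(lines) + "\n")
    return rpath
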