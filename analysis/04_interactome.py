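"""AP-MS interactome analysis on simulated TMT tables: median + bait
normalization, per-run log2 fold change over the mock pull-down with a paired
t test, Gaussian sigma estimation from the background histogram, the 2-sigma
reciprocal curved filter, master-list pooling, knockout-vs-parental grouped
deltas, and per-pathway zero tests with a repeated-measures ANOVA.

Writes results/analysis/interactome/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from cftrdms import interactome as im
from cftrdms import io as cio
from cftrdms import simulate as sim


def main() -> None:
    outdir = RESULTS / "interactome"
    outdir.mkdir(parents=True, exist_ok=True)

    cfg = sim.InteractomeSimConfig(
        n_proteins=2000, n_true_interactors=40, background_sigma=0.5,
        effect_sizes=(2.5,) * 40, n_replicates=3, both_cell_lines=True,
        ko_shift=0.8, seed=SEED + 40,
    )
    abundance, design, truth = sim.simulate_tmt_interactome(cfg)
    norm = im.normalize_abundances(abundance, design)

    pass_sets = {}
    for line in ("parental", "CANX_KO"):
        fc = im.log2fc_vs_mock(norm, design, cell_line=line)
        fit = im.estimate_sigma(fc["mean_log2fc"].drop("CFTR").dropna())
        calls = im.curved_filter(fc.drop(index="CFTR"), sigma=fit.sigma, c=0.8)
        pass_sets[line] = set(calls.index[calls["passes"]])
        spiked = set(truth.loc[truth["is_interactor"], "protein_id"])
        recall = len(pass_sets[line] & spiked) / len(spiked)
        fp = len(pass_sets[line] - spiked)
        print(f"{line}: sigma={fit.sigma:.3f} (x0={2*fit.sigma:.3f}); "
              f"{len(pass_sets[line])} interactors called, recall {recall:.2f}, "
              f"{fp} background calls")
        calls.assign(cell_line=line).to_csv(
            outdir / f"interactor_calls_{line}.tsv", sep="\t")

    master = im.master_interactor_list(pass_sets)
    cio.write_table(master, outdir / "master_list.tsv")
    print(f"master list: {len(master)} proteins pooled over both cell lines")

    deltas = im.grouped_delta(norm, design, master.index)
    cio.write_table(deltas, outdir / "grouped_deltas.tsv")

    classes = [c for c in im.PATHWAY_CLASSES if c != "other"]
    pathway = pd.Series("other", index=truth["protein_id"], name="pathway")
    for i, p in enumerate(truth.loc[truth["is_interactor"], "protein_id"]):
        pathway[p] = classes[i % len(classes)]
    tests = im.pathway_zero_tests(deltas["delta_log2"], pathway)
    cio.write_table(tests, outdir / "pathway_tests.tsv")
    print("pathway-level one-sample tests of the KO-minus-parental delta:")
    print(tests.round(4).to_string())

    # repeated-measures comparison of grouped abundances across cell lines
    long = pd.concat(
        [
            deltas[["log2_grouped_parental"]].rename(
                columns={"log2_grouped_parental": "value"}).assign(condition="parental"),
            deltas[["log2_grouped_ko"]].rename(
                columns={"log2_grouped_ko": "value"}).assign(condition="CANX_KO"),
        ]
    ).rename_axis("protein_id").reset_index()
    aov = im.rm_anova_gg(long, dv="value", within="condition", subject="protein_id")
    print(f"RM-ANOVA across cell lines: F={aov['F']:.2f}, "
          f"p(GG)={aov['p_gg']:.3g}, epsilon={aov['epsilon']:.3f}")


if __name__ == "__main__":
    main()
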