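"""Ground-truthed synthetic data for every pipeline stage.

Three generators mirror the three experimental arms:

* :func:`make_variant_library` + :func:`simulate_sort_seq` — a pool of
  recombinant cells, each expressing a single barcoded CFTR variant, sorted
  into four surface-immunostaining quartiles and sequenced per fraction.
* :func:`simulate_tmt_interactome` — multiplexed AP-MS abundance tables with
  a Gaussian background of log2 fold changes over a mock (GFP) pull-down and
  spiked true interactors.
* :func:`simulate_quench_traces` — single-cell halide-sensor quench traces
  following y(t) = y0 + A1*exp(-k1*t) with a flat pre-quench segment.

Single-cell surface fluorescence is modelled log-normal (Normal in log10),
the usual shape of cytometry intensity distributions. Sorting gates are
placed at the pooled 25/50/75 percentiles of each simulated replicate, so
gates are re-drawn per replicate exactly as independent sorts would be.
Calnexin knockout is modelled as a uniform multiplicative attenuation of
linear-scale true intensities; corrector treatment as per-variant fold
effects. Sequencing error is uniform substitution on the barcode; corrupted
barcodes that happen to collide with another whitelisted barcode are kept as
misassignments, the realistic failure mode an exact-match counter faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import FractionCountTable

UMI_LENGTH = 10
_BASES = np.array(list("ACGT"))

# Bimodal true-intensity model (log10 arbitrary units): most CF variants fall
# in a low-expression mode well below the WT-like mode, matching the broad
# loss-of-expression skew of the variant panel.
_LOW_MODE = (2.2, 0.25)
_WT_MODE = (3.0, 0.10)
_LOW_WEIGHT = 0.6

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SortSeqSimConfig:
    """Parameters of one sort-seq simulation (one replicate, one condition)."""

    n_variants: int
    cells_per_pool: int = 100_000
    reads_per_fraction: int = 200_000
    seq_error_rate: float = 0.001
    ko_attenuation: float = 0.26
    corrector_fold_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        if not (0.0 <= self.seq_error_rate < 0.25):
            raise ValueError("seq_error_rate must be in [0, 0.25)")
        if self.reads_per_fraction < self.n_variants:
            raise ValueError("reads_per_fraction must be >= n_variants")
        if self.ko_attenuation <= 0:
            raise ValueError("ko_attenuation must be > 0")
        for v, f in self.corrector_fold_effects.items():
            if f <= 0:
                raise ValueError(f"corrector fold effect for {v} must be > 0")


@dataclass(frozen=True)
class InteractomeSimConfig:
    """Parameters of a synthetic TMT AP-MS experiment."""

    n_proteins: int
    n_true_interactors: int
    background_sigma: float
    effect_sizes: tuple[float, ...]
    n_replicates: int = 3
    replicate_sigma: float = 0.1
    both_cell_lines: bool = False
    ko_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_interactors > self.n_proteins:
            raise ValueError("n_true_interactors cannot exceed n_proteins")
        if len(self.effect_sizes) != self.n_true_interactors:
            raise ValueError("effect_sizes length must equal n_true_interactors")
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be > 0")
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3")


def _random_unique_umis(n: int, rng: np.random.Generator) -> list[str]:
    if n > 4**UMI_LENGTH:
        raise ValueError(f"cannot draw {n} distinct UMIs of length {UMI_LENGTH}")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n, UMI_LENGTH))
        for row in block:
            umi = "".join(_BASES[row])
            if umi not in seen:
                seen.add(umi)
                out.append(umi)
                if len(out) == n:
                    break
    return out


def _random_variant_ids(n: int, rng: np.random.Generator) -> list[str]:
    """Synthetic missense-style ids with unique residue positions (cycled past 1480)."""
    ids: list[str] = []
    positions = rng.permutation(np.arange(1, 1481))
    aa = np.array(list(_AMINO))
    i = 0
    while len(ids) < n:
        pos = int(positions[i % 1480])
        wt, mut = rng.choice(aa, size=2, replace=False)
        vid = f"{wt}{pos}{mut}"
        if vid not in ids:
            ids.append(vid)
        i += 1
    return ids


def make_variant_library(n_variants: int, seed: int) -> pd.DataFrame:
    """Draw a ground-truth variant library.

    Returns a DataFrame with columns ``variant_id``, ``umi`` (unique 10-base
    barcode), ``true_mean_log10`` (log10 location of the single-cell surface
    fluorescence distribution, parental/vehicle condition) and ``cell_sd``
    (log10-scale spread). True intensities are bimodal: a low-expression mode
    and a WT-like mode.
    """
    if n_variants < 2:
        raise ValueError("n_variants must be >= 2")
    rng = np.random.default_rng(seed)
    umis = _random_unique_umis(n_variants, rng)
    ids = _random_variant_ids(n_variants, rng)
    low = rng.random(n_variants) < _LOW_WEIGHT
    mu = np.where(
        low,
        rng.normal(_LOW_MODE[0], _LOW_MODE[1], n_variants),
        rng.normal(_WT_MODE[0], _WT_MODE[1], n_variants),
    )
    sd = rng.uniform(0.15, 0.25, n_variants)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "umi": umis,
            "true_mean_log10": mu,
            "cell_sd": sd,
        }
    )


@dataclass
class SortSeqResult:
    """Output of one simulated sort-seq replicate, ground truth alongside."""

    table: FractionCountTable
    unmatched: np.ndarray  # reads per fraction whose corrupted UMI left the whitelist
    truth: pd.DataFrame  # variant_id, true_linear_mean, cells_frac1..4, true reads
    reads: list[pd.DataFrame] | None = None  # per fraction: umi, true_umi, true_variant


def condition_linear_means(
    library: pd.DataFrame,
    config: SortSeqSimConfig,
    cell_line: str = "parental",
    treatment: str = "vehicle",
) -> np.ndarray:
    """Linear-scale mean fluorescence per variant under a condition.

    The log-normal mean is 10**mu * exp((ln10 * sd)^2 / 2); knockout scales it
    by ``ko_attenuation`` and corrector treatment by the per-variant fold.
    """
    mu = library["true_mean_log10"].to_numpy(float)
    sd = library["cell_sd"].to_numpy(float)
    mean = 10.0**mu * np.exp((np.log(10.0) * sd) ** 2 / 2.0)
    if cell_line == "CANX_KO":
        mean = mean * config.ko_attenuation
    if treatment != "vehicle":
        folds = library["variant_id"].map(config.corrector_fold_effects).fillna(1.0)
        mean = mean * folds.to_numpy(float)
    return mean


def simulate_sort_seq(
    library: pd.DataFrame,
    config: SortSeqSimConfig,
    cell_line: str = "parental",
    treatment: str = "vehicle",
    replicate_id: str = "rep1",
    keep_reads: bool = False,
) -> SortSeqResult:
    """Simulate one FACS sort + per-fraction sequencing replicate.

    Cells are assigned uniformly to variants, draw log10 fluorescence from
    Normal(condition mean, cell_sd), and are gated at the pooled 25/50/75
    percentiles. Reads are drawn multinomially per fraction in proportion to
    the fraction's variant composition, then the barcode of each read is
    corrupted base-wise at ``seq_error_rate`` and re-assigned by exact match.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if config.reads_per_fraction == 0:
        raise ValueError("reads_per_fraction must be > 0")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, _stable_hash(cell_line), _stable_hash(treatment), _stable_hash(replicate_id)]
        )
    )
    n_var = len(library)
    mu_log = library["true_mean_log10"].to_numpy(float).copy()
    if cell_line == "CANX_KO":
        mu_log = mu_log + np.log10(config.ko_attenuation)
    if treatment != "vehicle":
        folds = library["variant_id"].map(config.corrector_fold_effects).fillna(1.0)
        mu_log = mu_log + np.log10(folds.to_numpy(float))
    sd = library["cell_sd"].to_numpy(float)

    cell_variant = rng.integers(0, n_var, size=config.cells_per_pool)
    log_f = rng.normal(mu_log[cell_variant], sd[cell_variant])
    lin_f = 10.0**log_f

    # Sorting gates at pooled quartiles, re-drawn per replicate.
    gates = np.quantile(log_f, [0.25, 0.5, 0.75])
    frac_idx = np.searchsorted(gates, log_f, side="right")  # 0..3

    fraction_means = np.array([lin_f[frac_idx == k].mean() for k in range(4)])

    umi_codes = np.array(
        [[_BASES.tolist().index(b) for b in u] for u in library["umi"]], dtype=np.int8
    )
    whitelist = {u: i for i, u in enumerate(library["umi"])}

    counts = np.zeros((n_var, 4), dtype=np.int64)
    true_counts = np.zeros((n_var, 4), dtype=np.int64)
    cells_per = np.zeros((n_var, 4), dtype=np.int64)
    unmatched = np.zeros(4, dtype=np.int64)
    reads_out: list[np.ndarray] | None = [] if keep_reads else None

    for k in range(4):
        in_frac = cell_variant[frac_idx == k]
        comp = np.bincount(in_frac, minlength=n_var).astype(float)
        cells_per[:, k] = comp.astype(np.int64)
        if comp.sum() == 0:
            raise RuntimeError("empty sorting fraction; increase cells_per_pool")
        draw = rng.multinomial(config.reads_per_fraction, comp / comp.sum())
        true_counts[:, k] = draw
        read_variant = np.repeat(np.arange(n_var), draw)
        counts[:, k] = draw
        corrupted_strings: dict[int, str] = {}
        if config.seq_error_rate > 0:
            err = rng.random((len(read_variant), UMI_LENGTH)) < config.seq_error_rate
            hit_rows = np.flatnonzero(err.any(axis=1))
            for row in hit_rows:
                codes = umi_codes[read_variant[row]].copy()
                mask = err[row]
                # uniform substitution to one of the three other bases
                shift = rng.integers(1, 4, size=int(mask.sum()))
                codes[mask] = (codes[mask] + shift) % 4
                umi = "".join(_BASES[codes])
                corrupted_strings[row] = umi
                counts[read_variant[row], k] -= 1
                j = whitelist.get(umi)
                if j is None:
                    unmatched[k] += 1
                else:
                    counts[j, k] += 1
        if reads_out is not None:
            read_umis = library["umi"].to_numpy()[read_variant].copy()
            for row, umi in corrupted_strings.items():
                read_umis[row] = umi
            reads_out.append(
                pd.DataFrame(
                    {
                        "umi": read_umis,
                        "true_umi": library["umi"].to_numpy()[read_variant],
                        "true_variant": library["variant_id"].to_numpy()[read_variant],
                    }
                )
            )

    table = FractionCountTable(
        counts=pd.DataFrame(
            counts,
            index=pd.Index(library["variant_id"], name="variant_id"),
            columns=[f"frac{k+1}" for k in range(4)],
        ),
        fraction_means=fraction_means,
        replicate_id=replicate_id,
        cell_line=cell_line,
        treatment=treatment,
    )
    truth = pd.DataFrame(
        {
            "variant_id": library["variant_id"],
            "true_linear_mean": condition_linear_means(library, config, cell_line, treatment),
            **{f"cells_frac{k+1}": cells_per[:, k] for k in range(4)},
            **{f"true_reads_frac{k+1}": true_counts[:, k] for k in range(4)},
        }
    )
    return SortSeqResult(table=table, unmatched=unmatched, truth=truth, reads=reads_out)


def _stable_hash(text: str) -> int:
    """Deterministic small hash of a short label (process-independent)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def simulate_tmt_interactome(
    config: InteractomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a TMT AP-MS experiment against a mock (GFP) control.

    Returns ``(abundance, design, truth)``. Background proteins carry a
    per-protein latent log2 offset over mock drawn Normal(0, background_sigma);
    true interactors are offset by ``effect_sizes``. Each run applies its own
    log-uniform channel loading factors so normalization is exercised. The
    bait protein row ``CFTR`` is present at high abundance in all non-mock
    channels. With ``both_cell_lines`` a matched CANX-KO arm is generated whose
    interactor offsets are shifted by ``ko_shift`` log2 units.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    is_true = np.zeros(n, dtype=bool)
    is_true[: config.n_true_interactors] = True
    effect = np.zeros(n)
    effect[: config.n_true_interactors] = np.asarray(config.effect_sizes, float)

    base = 10.0 ** rng.normal(5.0, 0.5, n)  # resting abundance per protein
    latent = rng.normal(0.0, config.background_sigma, n)
    latent[is_true] = effect[is_true]

    cell_lines = ["parental", "CANX_KO"] if config.both_cell_lines else ["parental"]
    cols: dict[str, np.ndarray] = {}
    design_rows = []
    for line in cell_lines:
        shift = config.ko_shift if line == "CANX_KO" else 0.0
        for r in range(1, config.n_replicates + 1):
            run = f"run{r}_{line}" if config.both_cell_lines else f"run{r}"
            load_bait = rng.uniform(np.log(0.5), np.log(2.0))
            load_mock = rng.uniform(np.log(0.5), np.log(2.0))
            noise_b = rng.normal(0.0, config.replicate_sigma, n)
            noise_m = rng.normal(0.0, config.replicate_sigma, n)
            off = np.where(is_true, latent + shift, latent)
            bait_ch = f"{run}_bait"
            mock_ch = f"{run}_mock"
            cols[bait_ch] = base * 2.0 ** (off + noise_b) * np.exp(load_bait)
            cols[mock_ch] = base * 2.0 ** noise_m * np.exp(load_mock)
            design_rows.append((bait_ch, run, "F508del", line, "vehicle", r))
            design_rows.append((mock_ch, run, "MOCK", line, "vehicle", r))

    abundance = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))
    # bait protein pulled down in bait channels, trace-level in mock
    bait_row = {}
    for ch, run, bait, line, trt, rep in design_rows:
        bait_row[ch] = 5e6 * rng.uniform(0.9, 1.1) if bait != "MOCK" else 1e3
    abundance.loc["CFTR"] = pd.Series(bait_row)
    design = pd.DataFrame(
        design_rows,
        columns=["channel", "run", "bait", "cell_line", "treatment", "replicate"],
    )
    truth = pd.DataFrame(
        {"protein_id": proteins, "is_interactor": is_true, "effect_size": effect}
    )
    return abundance, design, truth


def simulate_quench_traces(
    k1: float,
    y0: float,
    A1: float,
    noise_sd: float,
    n_cells: int,
    t_max: float,
    seed: int,
    n_replicates: int = 1,
    pre_fraction: float = 0.05,
    t_pre: float = 10.0,
) -> pd.DataFrame:
    """Simulate single-cell hYFP:mKate ratio observations around iodide addition.

    Each cell is observed once at a jittered time; a ``pre_fraction`` of cells
    are observed before quench (t < 0) at the plateau y0 + A1. Post-quench
    values follow y0 + A1*exp(-k1*t) + Normal(0, noise_sd).
    """
    if k1 < 0:
        raise ValueError("k1 must be >= 0")
    if A1 <= 0:
        raise ValueError("A1 must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(1, n_replicates + 1):
        pre = rng.random(n_cells) < pre_fraction
        t = np.where(
            pre,
            -rng.uniform(0.0, t_pre, n_cells),
            rng.uniform(0.0, t_max, n_cells),
        )
        clean = np.where(t < 0, y0 + A1, y0 + A1 * np.exp(-k1 * np.maximum(t, 0.0)))
        value = clean + (rng.normal(0.0, noise_sd, n_cells) if noise_sd > 0 else 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "time": t,
                    "value": value,
                    "cell_id": np.arange(n_cells),
                    "replicate": f"rep{rep}",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
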