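"""Synthetic patient cohorts with planted expression asymmetry and
methylation links.

The generative model follows the hypothesis the analysis is built to probe:
a gene's expression distribution acquires a tail because a minority patient
subgroup is shifted.  Each gene draws its main mode from
Normal(baseline_mean, baseline_sd) on the log2 scale and a tail subgroup of
fraction pi from Normal(baseline_mean + direction * delta, baseline_sd);
the relative size of the subgroup and the shift control the sign and
magnitude of the resulting skewness.

For a configurable fraction of "linked" genes the *same* patient subgroup
also carries a planted M-value shift on probes of a chosen functional
region — so the expression tail and the methylation difference are coupled
at the patient level.  When ``target_corr`` is set, the planted per-gene
methylation shifts are drawn so that their Pearson correlation with the
realized sample skewness of the linked genes equals the target (standard
correlated-Gaussian construction).

Everything derives from one seed through spawned sub-streams per gene, so a
fixed config reproduces bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import skewcore
from .convergence import ConvergenceSeries
from .enrich import GeneSetCollection
from .methlink import MethylationMatrix, REGIONS
from .skewcore import ExpressionMatrix


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Expression units are log2 intensities; methylation shifts are in M-value
    (log2-odds) units.  ``methyl_shift`` maps region -> planted tail shift
    for linked genes *with positive skew direction*; negative-direction
    linked genes receive the opposite sign (methylation change opposes the
    expression shift, the negative-correlation regime).  ``target_corr``
    (when set) is the planted Pearson correlation between linked genes'
    realized skewness and their per-region shift; ``methyl_shift_sd`` is the
    per-gene shift spread used when no target correlation is requested (with
    one, the spread follows from the correlation construction).
    ``linked_direction`` restricts linked genes to one skew direction
    (None = both).
    """

    n_genes: int = 200
    n_samples: int = 500
    tail_fraction: float = 0.1
    tail_shift: float = 3.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    fraction_negative_skew: float = 0.5
    n_probes_per_gene: int = 12
    region_probabilities: dict = field(
        default_factory=lambda: {"Promoter": 0.35, "UTR": 0.2, "Body": 0.45}
    )
    methyl_shift: dict = field(default_factory=lambda: {"Promoter": -1.0})
    methyl_shift_sd: float = 0.3
    methyl_noise_sd: float = 0.5
    probe_baseline_sd: float = 2.0
    linked_fraction: float = 0.0
    linked_direction: int | None = None
    target_corr: float | None = None
    n_background_sets: int = 20
    set_size: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_probes_per_gene"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if not 0 <= self.tail_fraction < 0.5:
            raise ValueError(f"tail_fraction must lie in [0, 0.5), got {self.tail_fraction}")
        if not 0 <= self.fraction_negative_skew <= 1:
            raise ValueError("fraction_negative_skew must lie in [0, 1]")
        if not 0 <= self.linked_fraction <= 1:
            raise ValueError("linked_fraction must lie in [0, 1]")
        if set(self.region_probabilities) - set(REGIONS):
            raise ValueError(f"regions must be among {REGIONS}")
        total = sum(self.region_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region probabilities sum to {total}, not 1")
        if self.linked_direction not in (1, -1, None):
            raise ValueError("linked_direction must be +1, -1 or None")
        if self.target_corr is not None and not -1 <= self.target_corr <= 1:
            raise ValueError("target_corr must lie in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Planted per-gene parameters: skew direction (+1/-1/0), tail fraction
    and shift, tail sample ids, linked flag, per-region methylation shifts."""

    table: pd.DataFrame  # index gene: direction, pi, delta, linked, dm_<region>
    tails: dict[str, list]

    def to_json_dict(self) -> dict:
        return {
            "genes": {
                gene: {
                    **{k: (None if pd.isna(v) else (int(v) if k in ("direction", "linked") else float(v)))
                       for k, v in row.items()},
                    "tail_samples": self.tails.get(gene, []),
                }
                for gene, row in self.table.to_dict(orient="index").items()
            }
        }


@dataclass
class SyntheticCohort:
    """All artifacts of one generated cohort."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    annotation: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: SyntheticTruth
    config: CohortConfig


def expected_skewness(pi: float, shift_in_sd: float) -> float:
    """Closed-form skewness of the two-component location-shift model.

    For X ~ (1-pi) N(0,1) + pi N(d,1), the third central moment is
    pi (1-pi) (1-2 pi) d^3 and the variance 1 + pi (1-pi) d^2, so the
    statistic's population value is
    d * (pi (1-pi) (1-2 pi))^(1/3) / sqrt(1 + pi (1-pi) d^2).
    Useful for sizing planted effects and as a test oracle."""
    d = shift_in_sd
    m3 = pi * (1 - pi) * (1 - 2 * pi) * d**3
    m2 = 1 + pi * (1 - pi) * d**2
    return float(np.sign(m3) * abs(m3) ** (1 / 3) / np.sqrt(m2))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate expression, matched methylation, probe annotation, gene sets
    and ground truth for one cohort.  See the module docstring for the model."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(3 + 2 * cfg.n_genes)
    cohort_rng = np.random.default_rng(streams[0])
    dm_rng = np.random.default_rng(streams[1])
    sets_rng = np.random.default_rng(streams[2])
    expr_streams = streams[3 : 3 + cfg.n_genes]
    meth_streams = streams[3 + cfg.n_genes :]

    genes = _gene_ids(cfg.n_genes)
    samples = _sample_ids(cfg.n_samples)
    n = cfg.n_samples

    # planted skew directions; pi = 0 or delta = 0 means no tail at all
    has_tail = cfg.tail_fraction > 0 and cfg.tail_shift != 0
    if has_tail:
        directions = np.where(
            cohort_rng.random(cfg.n_genes) < cfg.fraction_negative_skew, -1, 1
        )
    else:
        directions = np.zeros(cfg.n_genes, dtype=int)

    # linked genes come from the directed genes (optionally one direction)
    n_linked = int(round(cfg.linked_fraction * cfg.n_genes))
    if cfg.linked_direction is None:
        candidates = np.flatnonzero(directions != 0)
    else:
        candidates = np.flatnonzero(directions == cfg.linked_direction)
    if n_linked > len(candidates):
        n_linked = len(candidates)
    linked_idx = (
        cohort_rng.choice(candidates, size=n_linked, replace=False)
        if n_linked
        else np.array([], dtype=int)
    )
    linked = np.zeros(cfg.n_genes, dtype=bool)
    linked[linked_idx] = True

    tail_size = int(round(cfg.tail_fraction * n)) if has_tail else 0
    expr = np.empty((cfg.n_genes, n))
    tails: dict[str, list] = {}
    for i, gene in enumerate(genes):
        rng = np.random.default_rng(expr_streams[i])
        values = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
        if tail_size and directions[i] != 0:
            tail_pos = rng.choice(n, size=tail_size, replace=False)
            values[tail_pos] = rng.normal(
                cfg.baseline_mean + directions[i] * cfg.tail_shift,
                cfg.baseline_sd,
                size=tail_size,
            )
            tails[gene] = [samples[j] for j in np.sort(tail_pos)]
        else:
            tails[gene] = []
        expr[i] = values
    expression = ExpressionMatrix(
        data=pd.DataFrame(expr, index=genes, columns=samples), platform="other"
    )

    # planted per-gene methylation shifts for linked genes, per region.
    # Sign opposes the skew direction: positive-direction genes get
    # methyl_shift as given (negative by default), negative-direction genes
    # the opposite.  With target_corr, shifts are a linear function of the
    # realized standardized skewness plus independent noise, scaled so the
    # positive-direction group mean equals methyl_shift and the overall
    # Pearson correlation with skewness equals the target.
    dm_planted = pd.DataFrame(np.nan, index=genes, columns=[f"dm_{r}" for r in REGIONS])
    if n_linked:
        linked_genes = [genes[i] for i in linked_idx]
        linked_dirs = directions[linked_idx].astype(float)
        z_noise = dm_rng.standard_normal(n_linked)
        use_corr = cfg.target_corr is not None and n_linked >= 3
        if use_corr:
            realized = skewcore.compute_skewness(expression).loc[
                linked_genes, "skewness"
            ].to_numpy(float)
            sd = realized.std()
            z_s = (realized - realized.mean()) / sd if sd > 0 else np.zeros(n_linked)
            rho = cfg.target_corr
            structured = rho * z_s + np.sqrt(1 - rho**2) * z_noise
            ref = 1.0 if (linked_dirs > 0).any() else -1.0
            mean_ref = float((rho * z_s)[linked_dirs == ref].mean())
        for region, shift in cfg.methyl_shift.items():
            col = f"dm_{region}"
            if use_corr and abs(mean_ref) > 0.05:
                scale = ref * shift / mean_ref
                dm_planted.loc[linked_genes, col] = scale * structured
            elif use_corr:
                # single tight cluster: center the structured part on the
                # direction-signed shift instead
                dm_planted.loc[linked_genes, col] = (
                    linked_dirs * shift + cfg.methyl_shift_sd * structured
                )
            else:
                dm_planted.loc[linked_genes, col] = (
                    linked_dirs * shift + cfg.methyl_shift_sd * z_noise
                )

    # methylation probes: baseline level per probe, noise per sample,
    # planted tail shift on linked genes' probes of shifted regions
    region_names = list(cfg.region_probabilities)
    region_p = np.array([cfg.region_probabilities[r] for r in region_names])
    probe_rows, probe_ids, probe_genes, probe_regions = [], [], [], []
    for i, gene in enumerate(genes):
        rng = np.random.default_rng(meth_streams[i])
        regions = rng.choice(region_names, size=cfg.n_probes_per_gene, p=region_p)
        baselines = rng.normal(0.0, cfg.probe_baseline_sd, size=cfg.n_probes_per_gene)
        block = baselines[:, None] + rng.normal(
            0.0, cfg.methyl_noise_sd, size=(cfg.n_probes_per_gene, n)
        )
        if linked[i] and tails[gene]:
            tail_pos = [samples.index(s) for s in tails[gene]]
            for j, region in enumerate(regions):
                shift = dm_planted.loc[gene, f"dm_{region}"]
                if pd.notna(shift):
                    block[j, tail_pos] += shift
        for j in range(cfg.n_probes_per_gene):
            probe_ids.append(f"{gene}_p{j + 1}")
            probe_genes.append(gene)
            probe_regions.append(regions[j])
        probe_rows.append(block)
    meth_data = pd.DataFrame(
        np.vstack(probe_rows) if probe_rows else np.empty((0, n)),
        index=probe_ids,
        columns=samples,
    )
    methylation = MethylationMatrix(data=meth_data, origin="native-M")
    annotation = pd.DataFrame(
        {"gene_id": probe_genes, "region": probe_regions}, index=probe_ids
    )
    annotation.index.name = "probe_id"

    gene_sets = _make_gene_sets(genes, directions, cfg, sets_rng)

    truth_table = pd.DataFrame(
        {
            "direction": directions,
            "pi": np.where(directions != 0, cfg.tail_fraction, 0.0),
            "delta": np.where(directions != 0, cfg.tail_shift, 0.0),
            "linked": linked.astype(int),
            **{c: dm_planted[c] for c in dm_planted.columns},
        },
        index=genes,
    )
    truth = SyntheticTruth(table=truth_table, tails=tails)
    return SyntheticCohort(
        expression=expression,
        methylation=methylation,
        annotation=annotation,
        gene_sets=gene_sets,
        truth=truth,
        config=cfg,
    )


def _make_gene_sets(
    genes: list[str], directions: np.ndarray, cfg: CohortConfig, rng: np.random.Generator
) -> GeneSetCollection:
    """Planted sets drawn from the positive- and negative-skew gene groups
    (when present) plus random background sets over all genes."""
    sets: dict[str, frozenset] = {}
    modules: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    gene_arr = np.asarray(genes)
    for label, direction in (("POS_SKEW_SET", 1), ("NEG_SKEW_SET", -1)):
        pool = gene_arr[directions == direction]
        if len(pool) == 0:
            continue
        size = min(cfg.set_size, len(pool))
        sets[label] = frozenset(rng.choice(pool, size=size, replace=False))
        modules[label] = "Planted"
        descriptions[label] = f"genes with planted direction {direction:+d}"
    for i in range(cfg.n_background_sets):
        name = f"RANDOM_SET_{i + 1:02d}"
        size = min(cfg.set_size, len(gene_arr))
        sets[name] = frozenset(rng.choice(gene_arr, size=size, replace=False))
        modules[name] = "Background"
        descriptions[name] = "uniform random gene set"
    return GeneSetCollection(sets=sets, descriptions=descriptions, modules=modules)


def generate_convergence_series(
    a: float,
    b: float,
    L: float,
    sizes,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ConvergenceSeries:
    """Series s_n = a * exp(-b * n) + L + Normal(0, noise_sd) at each size.

    Requires b > 0 and a non-empty, strictly increasing size list."""
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("empty size list")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")
    if b <= 0:
        raise ValueError(f"decay rate b must be positive, got {b}")
    rng = np.random.default_rng(seed)
    values = a * np.exp(-b * sizes) + L + rng.normal(0.0, noise_sd, size=sizes.size)
    return ConvergenceSeries(
        sizes=sizes, values=values, repeats=1, dispersion=np.zeros(sizes.size)
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write all cohort artifacts: expression/methylation TSV, probe
    annotation TSV, gene sets GMT, truth JSON.  Returns the path map."""
    from . import io as skio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "annotation": outdir / "probes.tsv",
        "gene_sets": outdir / "sets.gmt",
        "truth": outdir / "truth.json",
    }
    skio.write_matrix(cohort.expression.data, paths["expression"], feature_name="gene_id")
    skio.write_matrix(cohort.methylation.data, paths["methylation"], feature_name="probe_id")
    cohort.annotation.to_csv(paths["annotation"], sep="\t")
    skio.write_gmt(cohort.gene_sets, paths["gene_sets"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return paths
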