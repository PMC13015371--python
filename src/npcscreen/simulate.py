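"""Seeded synthetic data with known ground truth.

Two generators stand in for the study's raw data so every downstream stage
is testable end to end:

* :func:`simulate_well_traces` — exponential well growth with
  genotype-dependent doubling times, an additive treatment effect on the
  doubling time, multiplicative log-normal measurement noise, and a
  configurable fraction of failing wells (growth stops before 48 h), which
  exercises the outlier rules.
* :func:`simulate_deg_tables` — paired genotype and treatment differential
  expression contrast tables over a shared gene universe, with planted
  corrected / worsened / novel categories consistent with the
  direction-concordance sign rule.

Both draw from a single ``numpy.random.default_rng(seed)`` stream per call,
in the documented order, so identical configs give bit-identical output and
the draw procedure can be replayed independently in tests.

Deterministic draw order, growth simulation
-------------------------------------------
1. per-line baseline doubling times: for genotype in sorted order, for each
   line index, one ``rng.normal(mean, sd)`` draw, redrawn while <= 1 h;
2. one uniform draw per well in well order (plate, genotype sorted, line,
   condition untreated-then-treated, replicate): ``rng.random(n_wells)``,
   failure iff draw < fail_fraction (Bernoulli);
3. failure times: ``rng.uniform(12, 44, n_wells)`` (used only for failing
   wells);
4. measurement noise: ``rng.normal(0, sigma, (n_wells, n_times))`` with
   ``sigma = sqrt(ln(1 + noise_cv^2))``; the multiplier is
   ``exp(eps - sigma^2/2)`` (unit mean).  ``noise_cv = 0`` gives the exact
   noiseless model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .concordance import ContrastTable, DegRecord
from .errors import ConfigurationError
from .growth import WellTrace

MIN_ABS_LOG2FC = math.log2(1.5)  # planted DEGs clear the default FC >= |1.5| cut


class GrowthSimConfig(BaseModel):
    """Configuration of the synthetic growth-curve experiment.

    Defaults mirror the screen design: 120 h of culture imaged every 12 h,
    4 replicate wells per line and condition, slower-growing trisomic lines
    (T21 42 +/- 6 h baseline doubling time vs euploid 32 +/- 3 h) and a
    treatment that shortens the doubling time by 9 h in T21 lines and 3 h
    in euploid lines.
    """

    model_config = ConfigDict(extra="forbid")

    n_lines_per_genotype: int = Field(default=4, ge=1)
    replicates_per_condition: int = Field(default=4, ge=1)
    n_plates: int = Field(default=1, ge=1)
    duration_h: float = Field(default=120.0, gt=0)
    interval_h: float = Field(default=12.0, gt=0)
    n0: float = Field(default=5000.0, gt=0)
    baseline_dt_mean_by_genotype: dict[str, float] = Field(
        default_factory=lambda: {"Eup": 32.0, "T21": 42.0}
    )
    baseline_dt_sd_by_genotype: dict[str, float] = Field(
        default_factory=lambda: {"Eup": 3.0, "T21": 6.0}
    )
    treatment_dt_effect_h: float | dict[str, float] = Field(
        default_factory=lambda: {"Eup": -3.0, "T21": -9.0}
    )
    molecule: str = "fasudil"
    concentration_uM: float = 8.0
    noise_cv: float = Field(default=0.05, ge=0)
    fail_fraction: float = Field(default=0.05, ge=0, lt=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GrowthSimConfig":
        n_steps = self.duration_h / self.interval_h
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                "duration_h must be an integer multiple of interval_h; got "
                f"duration_h={self.duration_h}, interval_h={self.interval_h}"
            )
        for name, mapping in (
            ("baseline_dt_mean_by_genotype", self.baseline_dt_mean_by_genotype),
            ("baseline_dt_sd_by_genotype", self.baseline_dt_sd_by_genotype),
        ):
            for gt, val in mapping.items():
                if val <= 0:
                    raise ValueError(f"{name}[{gt}] must be > 0, got {val}")
        if set(self.baseline_dt_mean_by_genotype) != set(self.baseline_dt_sd_by_genotype):
            raise ValueError(
                "baseline_dt_mean_by_genotype and baseline_dt_sd_by_genotype "
                "must cover the same genotypes"
            )
        return self

    def effect_for(self, genotype: str) -> float:
        if isinstance(self.treatment_dt_effect_h, dict):
            return self.treatment_dt_effect_h.get(genotype, 0.0)
        return self.treatment_dt_effect_h


class DegSimConfig(BaseModel):
    """Configuration of the synthetic DEG contrast-table pair.

    Default fractions echo the scale of the trisomy/treatment analysis:
    a large genotype signature, of which a modest fraction responds to
    treatment, 83.5% of responding overlap genes corrected (opposite-sign
    fold change) and 17.8% of treatment DEGs novel.
    """

    model_config = ConfigDict(extra="forbid")

    n_genes: int = Field(default=20000, ge=1)
    frac_genotype_dys: float = Field(default=0.40, ge=0, le=1)
    frac_treatment_responsive: float = Field(default=0.17, ge=0, le=1)
    frac_corrected: float = Field(default=0.835, ge=0, le=1)
    frac_novel: float = Field(default=0.178, ge=0, le=1)
    effect_log2fc_mean: float = Field(default=1.0, gt=0)
    effect_log2fc_sd: float = Field(default=0.35, gt=0)
    frac_chr21: float = Field(default=0.02, ge=0, le=1)
    seed: int = 0

    def category_counts(self) -> dict[str, int]:
        """Planted category counts; raises when a nonzero fraction rounds to zero."""
        n_dys = round(self.frac_genotype_dys * self.n_genes)
        n_overlap = round(self.frac_treatment_responsive * n_dys)
        n_corrected = round(self.frac_corrected * n_overlap)
        n_worsened = n_overlap - n_corrected
        if self.frac_novel >= 1.0:
            raise ConfigurationError("frac_novel must be < 1 (field frac_novel)")
        n_novel = round(self.frac_novel / (1.0 - self.frac_novel) * n_overlap)
        for name, frac, count in (
            ("frac_genotype_dys", self.frac_genotype_dys, n_dys),
            ("frac_treatment_responsive", self.frac_treatment_responsive, n_overlap),
            ("frac_corrected", self.frac_corrected, n_corrected),
            ("frac_novel", self.frac_novel, n_novel),
        ):
            if frac > 0 and count < 1:
                raise ConfigurationError(
                    f"expected count for {name}={frac} is < 1 at n_genes={self.n_genes} "
                    f"(field {name})"
                )
        if n_dys + n_novel > self.n_genes:
            raise ConfigurationError(
                "planted DEG counts exceed the gene universe (fields "
                "frac_genotype_dys/frac_novel)"
            )
        return {
            "dysregulated": n_dys,
            "overlap": n_overlap,
            "corrected": n_corrected,
            "worsened": n_worsened,
            "novel": n_novel,
        }


@dataclass
class GroundTruth:
    """Planted truth for simulated wells and genes.

    ``wells`` maps well_id -> {dt_h, fail, genotype, line_id, condition};
    ``genes`` maps gene_id -> category in {corrected_down, corrected_up,
    worsened, novel, null}.  Exactly one record per simulated well/gene.
    """

    wells: dict[str, dict] = field(default_factory=dict)
    genes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"wells": self.wells, "genes": self.genes}, indent=1, sort_keys=True)
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(wells=payload.get("wells", {}), genes=payload.get("genes", {}))


# ---------------------------------------------------------------------------
# growth traces
# ---------------------------------------------------------------------------


def _enumerate_wells(config: GrowthSimConfig) -> list[dict]:
    """Fixed well enumeration order shared by all stochastic draws."""
    wells = []
    genotypes = sorted(config.baseline_dt_mean_by_genotype)
    for plate in range(1, config.n_plates + 1):
        for gt in genotypes:
            for line in range(1, config.n_lines_per_genotype + 1):
                line_id = f"{'EU' if gt == 'Eup' else 'TS'}{line}" if gt in ("Eup", "T21") else f"{gt}{line}"
                for condition in ("untreated", "treated"):
                    for rep in range(1, config.replicates_per_condition + 1):
                        wells.append(
                            {
                                "plate_id": f"P{plate}",
                                "genotype": gt,
                                "line_key": (gt, line),
                                "line_id": line_id,
                                "condition": condition,
                                "well_id": f"P{plate}:{line_id}:{condition}:{rep}",
                            }
                        )
    return wells


def simulate_well_traces(
    config: GrowthSimConfig,
) -> tuple[list[WellTrace], GroundTruth]:
    """Simulate one screen's worth of well traces with planted truth.

    A non-failing well with planted doubling time ``d`` has expected value
    ``n0 * 2**(t/d)`` at time ``t``, perturbed by multiplicative log-normal
    noise with coefficient of variation ``noise_cv``.  Failing wells grow
    only until the last imaging time before a failure time drawn uniformly
    from [12 h, 44 h], then decline, so they can never exhibit 48 h of
    continuous growth.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = sorted(config.baseline_dt_mean_by_genotype)

    # 1. per-line baseline doubling times
    line_dt: dict[tuple[str, int], float] = {}
    for gt in genotypes:
        mean = config.baseline_dt_mean_by_genotype[gt]
        sd = config.baseline_dt_sd_by_genotype[gt]
        for line in range(1, config.n_lines_per_genotype + 1):
            draw = rng.normal(mean, sd)
            while draw <= 1.0:
                draw = rng.normal(mean, sd)
            line_dt[(gt, line)] = float(draw)

    wells = _enumerate_wells(config)
    n_wells = len(wells)
    times = np.arange(0.0, config.duration_h + 0.5 * config.interval_h, config.interval_h)
    n_times = times.size

    # 2-4. fail flags, fail times, noise
    fail_flags = rng.random(n_wells) < config.fail_fraction
    fail_times = rng.uniform(12.0, 44.0, n_wells)
    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    if sigma > 0:
        eps = rng.normal(0.0, sigma, (n_wells, n_times))
        multipliers = np.exp(eps - 0.5 * sigma**2)
    else:
        multipliers = np.ones((n_wells, n_times))

    traces: list[WellTrace] = []
    truth = GroundTruth()
    for i, w in enumerate(wells):
        dt = line_dt[w["line_key"]]
        if w["condition"] == "treated":
            dt = max(dt + config.effect_for(w["genotype"]), 1.0)
        if fail_flags[i]:
            # growth stops at the last imaging time before the drawn failure
            # time, so a failing well can never show >= 48 h of sampled
            # monotone growth; the decline (4%/h) dominates the noise
            t_plateau = math.floor(fail_times[i] / config.interval_h) * config.interval_h
            grown = config.n0 * np.power(2.0, np.minimum(times, t_plateau) / dt)
            model = grown * np.exp(-0.04 * np.maximum(times - t_plateau, 0.0))
        else:
            model = config.n0 * np.power(2.0, times / dt)
        values = model * multipliers[i]
        traces.append(
            WellTrace(
                plate_id=w["plate_id"],
                well_id=w["well_id"],
                line_id=w["line_id"],
                genotype=w["genotype"],
                condition=w["condition"],
                molecule=config.molecule if w["condition"] == "treated" else "",
                concentration_uM=(
                    config.concentration_uM if w["condition"] == "treated" else None
                ),
                times=tuple(times),
                values=tuple(values),
            )
        )
        truth.wells[w["well_id"]] = {
            "dt_h": float(dt),
            "fail": bool(fail_flags[i]),
            "genotype": w["genotype"],
            "line_id": w["line_id"],
            "condition": w["condition"],
        }
    return traces, truth


# ---------------------------------------------------------------------------
# DEG contrast tables
# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _truncated_magnitudes(
    rng: np.random.Generator, n: int, mean: float, sd: float, minimum: float
) -> np.ndarray:
    """Normal(mean, sd) magnitudes, redrawn (vectorized rejection) until >= minimum."""
    out = rng.normal(mean, sd, n)
    bad = out < minimum
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < minimum
    return out


def simulate_deg_tables(
    config: DegSimConfig,
) -> tuple[ContrastTable, ContrastTable, GroundTruth]:
    """Simulate a genotype contrast and a treatment contrast with planted truth.

    Draw order (one rng): gene permutation; chromosome-21 subset; genotype
    signs; genotype magnitudes; treatment magnitudes for overlap genes; novel
    signs; novel magnitudes; null log2fc for both tables; planted p-values
    for both tables; null p-values for both tables.

    Planted DEGs carry adjusted p in (1e-6, 0.049] and |fold change| >= 1.5;
    null genes carry p in (0.0501, 1] and |log2fc| < log2(1.5), so the
    default thresholds separate them exactly.
    """
    counts = config.category_counts()
    n = config.n_genes
    rng = np.random.default_rng(config.seed)
    ids = np.array(_gene_ids(n))

    perm = rng.permutation(n)
    dys_idx = perm[: counts["dysregulated"]]
    novel_idx = perm[counts["dysregulated"] : counts["dysregulated"] + counts["novel"]]
    overlap_idx = dys_idx[: counts["overlap"]]
    corrected_idx = overlap_idx[: counts["corrected"]]
    worsened_idx = overlap_idx[counts["corrected"] :]

    n_chr21 = round(config.frac_chr21 * n)
    chr21_idx = rng.choice(n, size=n_chr21, replace=False) if n_chr21 else np.array([], dtype=int)
    chromosome = np.full(n, "1", dtype=object)
    chromosome[chr21_idx] = "21"

    geno_sign = np.zeros(n)
    geno_sign[dys_idx] = rng.choice([-1.0, 1.0], size=dys_idx.size)
    geno_mag = np.zeros(n)
    geno_mag[dys_idx] = _truncated_magnitudes(
        rng, dys_idx.size, config.effect_log2fc_mean, config.effect_log2fc_sd, MIN_ABS_LOG2FC
    )

    treat_sign = np.zeros(n)
    treat_mag = np.zeros(n)
    treat_sign[corrected_idx] = -geno_sign[corrected_idx]
    treat_sign[worsened_idx] = geno_sign[worsened_idx]
    treat_mag[overlap_idx] = _truncated_magnitudes(
        rng, overlap_idx.size, config.effect_log2fc_mean, config.effect_log2fc_sd, MIN_ABS_LOG2FC
    )
    treat_sign[novel_idx] = rng.choice([-1.0, 1.0], size=novel_idx.size)
    treat_mag[novel_idx] = _truncated_magnitudes(
        rng, novel_idx.size, config.effect_log2fc_mean, config.effect_log2fc_sd, MIN_ABS_LOG2FC
    )

    # null background: small non-zero log2fc, clipped inside the FC 1.5 band
    geno_null = np.setdiff1d(np.arange(n), dys_idx, assume_unique=False)
    treat_deg_idx = np.concatenate([overlap_idx, novel_idx])
    treat_null = np.setdiff1d(np.arange(n), treat_deg_idx, assume_unique=False)
    geno_l2fc = geno_sign * geno_mag
    treat_l2fc = treat_sign * treat_mag
    for null_idx, arr in ((geno_null, geno_l2fc), (treat_null, treat_l2fc)):
        small = np.clip(rng.normal(0.0, 0.1, null_idx.size), -0.5, 0.5)
        small[small == 0.0] = 1e-6
        arr[null_idx] = small

    geno_p = np.empty(n)
    treat_p = np.empty(n)
    geno_p[dys_idx] = rng.uniform(1e-6, 0.049, dys_idx.size)
    treat_p[treat_deg_idx] = rng.uniform(1e-6, 0.049, treat_deg_idx.size)
    geno_p[geno_null] = rng.uniform(0.0501, 1.0, geno_null.size)
    treat_p[treat_null] = rng.uniform(0.0501, 1.0, treat_null.size)

    genotype_table = ContrastTable.from_arrays(
        name="T21Unt_vs_EupUnt",
        gene_ids=ids,
        log2fc=geno_l2fc,
        p_adj=geno_p,
        chromosome=chromosome,
    )
    treatment_table = ContrastTable.from_arrays(
        name="T21Trt_vs_T21Unt",
        gene_ids=ids,
        log2fc=treat_l2fc,
        p_adj=treat_p,
        chromosome=chromosome,
    )

    truth = GroundTruth()
    categories = np.full(n, "null", dtype=object)
    down = treat_l2fc < 0
    categories[corrected_idx] = np.where(down[corrected_idx], "corrected_down", "corrected_up")
    categories[worsened_idx] = "worsened"
    categories[novel_idx] = "novel"
    truth.genes = {str(g): str(c) for g, c in zip(ids, categories)}
    return genotype_table, treatment_table, truth


# ---------------------------------------------------------------------------
# exact-count constructors (synthetic stand-ins for published contrast tables)
# ---------------------------------------------------------------------------


def make_partition_tables(
    n_corrected_down: int,
    n_corrected_up: int,
    n_worsened: int,
    n_novel: int,
    n_genotype_only: int = 0,
    n_null: int = 0,
    seed: int = 0,
    abs_fc_min: float = 1.5,
    genotype_name: str = "genotype",
    treatment_name: str = "treatment",
) -> tuple[ContrastTable, ContrastTable, GroundTruth]:
    """Synthetic contrast-table pair with exact planted partition counts.

    Constructs tables whose thresholded comparison yields exactly the given
    corrected-down / corrected-up / worsened / novel counts (plus optional
    genotype-only DEGs and null genes).  Used to exercise the pipeline on
    the marginal structure of published comparisons whose underlying tables
    are not redistributed here; the gene content is synthetic.
    """
    rng = np.random.default_rng(seed)
    n = n_corrected_down + n_corrected_up + n_worsened + n_novel + n_genotype_only + n_null
    ids = np.array(_gene_ids(n))
    min_mag = math.log2(abs_fc_min) if abs_fc_min > 1 else 0.1
    mag = lambda m: _truncated_magnitudes(rng, m, min_mag + 0.5, 0.3, min_mag + 1e-9)

    geno_l2fc = np.zeros(n)
    treat_l2fc = np.zeros(n)
    geno_p = np.full(n, 0.9)
    treat_p = np.full(n, 0.9)
    categories = np.full(n, "null", dtype=object)
    cursor = 0

    def take(m: int) -> np.ndarray:
        nonlocal cursor
        sl = np.arange(cursor, cursor + m)
        cursor += m
        return sl

    cd = take(n_corrected_down)  # genotype up, treatment down
    geno_l2fc[cd], treat_l2fc[cd] = mag(cd.size), -mag(cd.size)
    categories[cd] = "corrected_down"
    cu = take(n_corrected_up)  # genotype down, treatment up
    geno_l2fc[cu], treat_l2fc[cu] = -mag(cu.size), mag(cu.size)
    categories[cu] = "corrected_up"
    wo = take(n_worsened)
    sign = rng.choice([-1.0, 1.0], wo.size)
    geno_l2fc[wo], treat_l2fc[wo] = sign * mag(wo.size), sign * mag(wo.size)
    categories[wo] = "worsened"
    nv = take(n_novel)
    treat_l2fc[nv] = rng.choice([-1.0, 1.0], nv.size) * mag(nv.size)
    categories[nv] = "novel"
    go = take(n_genotype_only)
    geno_l2fc[go] = rng.choice([-1.0, 1.0], go.size) * mag(go.size)
    nu = take(n_null)
    geno_l2fc[nu] = 0.01
    treat_l2fc[nu] = 0.01

    geno_deg = np.concatenate([cd, cu, wo, go]).astype(int)
    treat_deg = np.concatenate([cd, cu, wo, nv]).astype(int)
    geno_p[geno_deg] = rng.uniform(1e-6, 0.049, geno_deg.size)
    treat_p[treat_deg] = rng.uniform(1e-6, 0.049, treat_deg.size)

    genotype_table = ContrastTable.from_arrays(
        name=genotype_name, gene_ids=ids, log2fc=geno_l2fc, p_adj=geno_p
    )
    treatment_table = ContrastTable.from_arrays(
        name=treatment_name, gene_ids=ids, log2fc=treat_l2fc, p_adj=treat_p
    )
    truth = GroundTruth(genes={str(g): str(c) for g, c in zip(ids, categories)})
    return genotype_table, treatment_table, truth


def make_shared_tables(
    n_shared_same_direction: int,
    n_shared_opposite: int,
    n_a_only: int,
    n_b_only: int,
    n_larger_in_a: int,
    seed: int = 0,
    name_a: str = "a",
    name_b: str = "b",
) -> tuple[ContrastTable, ContrastTable]:
    """Synthetic thresholded table pair with exact shared-response structure.

    ``n_larger_in_a`` of the same-direction shared genes get the larger
    |fold change| in table a; the rest get it in table b.
    """
    if n_larger_in_a > n_shared_same_direction:
        raise ConfigurationError("n_larger_in_a cannot exceed n_shared_same_direction")
    rng = np.random.default_rng(seed)
    n = n_shared_same_direction + n_shared_opposite + n_a_only + n_b_only
    ids = _gene_ids(n)
    rec_a: list[DegRecord] = []
    rec_b: list[DegRecord] = []
    cursor = 0

    def draw(sign: float, base: float) -> float:
        return sign * (base + float(rng.uniform(0.0, 0.3)))

    for i in range(n_shared_same_direction):
        g = ids[cursor]
        cursor += 1
        sign = float(rng.choice([-1.0, 1.0]))
        big, small = draw(sign, 1.5), draw(sign, 0.8)
        a_mag, b_mag = (big, small) if i < n_larger_in_a else (small, big)
        rec_a.append(DegRecord.from_log2fc(g, a_mag, 0.01))
        rec_b.append(DegRecord.from_log2fc(g, b_mag, 0.01))
    for _ in range(n_shared_opposite):
        g = ids[cursor]
        cursor += 1
        sign = float(rng.choice([-1.0, 1.0]))
        rec_a.append(DegRecord.from_log2fc(g, draw(sign, 1.0), 0.01))
        rec_b.append(DegRecord.from_log2fc(g, draw(-sign, 1.0), 0.01))
    for _ in range(n_a_only):
        g = ids[cursor]
        cursor += 1
        rec_a.append(DegRecord.from_log2fc(g, draw(float(rng.choice([-1.0, 1.0])), 1.0), 0.01))
    for _ in range(n_b_only):
        g = ids[cursor]
        cursor += 1
        rec_b.append(DegRecord.from_log2fc(g, draw(float(rng.choice([-1.0, 1.0])), 1.0), 0.01))
    return ContrastTable(name=name_a, records=rec_a), ContrastTable(name=name_b, records=rec_b)
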