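"""Synthetic barcoded-clone experiments with ground truth.

Emulates an in vitro chemoresistance study on DNA-barcoded AML cells end to
end: a clone population with latent growth, drug-survival and
leukemia-initiating attributes; kill-and-regrow treatment courses; paired
technical-replicate sequencing; and xenograft limiting-dilution engraftment.
Every draw descends from one master seed, so the full benchmark is
reproducible byte for byte, and a manifest records the planted ground truth
(resistant set, high-L-IC set, true population L-IC frequency).

Model sketch
------------
* T0 clone frequencies are a symmetric-Dirichlet draw (heavy-tailed for
  alpha < 1); a small set of clones planted at intermediate frequency ranks
  is marked chemoresistant: high drug survival (a declared multiplier over
  the baseline), slower growth and (for most of them) elevated
  leukemia-initiating-cell content -- the stem-like phenotype.
* A treatment course is a stochastic kill (per-clone binomial survival,
  scaled so the expected bulk kill matches the regimen's target) followed by
  deterministic exponential regrowth at each clone's rate until the culture
  returns to its starting cell number ("Trelapse").  Hypomethylating-agent
  (DAC) combination is modeled phenomenologically: resistant clones still
  survive the kill but their regrowth is strongly suppressed, while the
  remaining clones regrow slightly faster.
* Sequencing draws each technical replicate as an independent multinomial
  of the requested depth over clone frequencies (optional
  Dirichlet-multinomial overdispersion).
* A xenografted mouse receives per-clone L-ICs as independent Poissons of
  dose x frequency x L-IC fraction; the mouse is positive iff it received
  at least one L-IC (single-hit model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .barcode_io import (
    BarcodeLibrary,
    write_counts,
    write_library,
    write_sample_sheet,
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the simulated study.  See docs/methods.md for rationale.

    Defaults reproduce the printed magnitudes of the emulated experiments:
    a few hundred active barcodes from a ~2600-barcode library, >99% bulk
    kill with regrowth to the starting cell number, a small planted
    resistant set with a >=50x survival advantage that ends up dominating
    chemoresistant relapses (~7-9x summed-frequency expansion), and paired
    technical replicates at the conventional 1e5-read normalization depth.
    """

    seed: int = 0
    library_size: int = 2600
    n_clones: int | None = None  # None: draw uniformly in [210, 330]
    #: T0 clone-size law.  The population models the *detected* clone set
    #: (a few hundred barcodes above the sequencing floor), so the default
    #: is a lognormal spread around the even share 1/n; "dirichlet" gives a
    #: raw symmetric-Dirichlet draw whose heavy tail extends below the
    #: detection floor.
    initial_distribution: str = "lognormal"
    lognormal_sigma: float = 0.8
    dirichlet_alpha: float = 0.8
    n_resistant: int = 5
    resistant_rank_start: int = 11  # 0-based frequency rank of first planted clone
    resistant_survival_multiplier: float = 50.0
    resistant_growth_factor: float = 0.85  # slow, stem-like growth
    survival_noise_sd: float = 0.0  # lognormal sigma on per-clone survival weight
    #: net per-day growth during recovery; 0.18/day regrows a >99%-depleted
    #: culture back to its starting size in ~30 days, the relapse window of
    #: the emulated experiments, and matches the 30-day untreated harvest.
    growth_rate_mean: float = 0.18
    growth_rate_sd: float = 0.01
    n0_cells: float = 1e9  # cells at treatment initiation (regrowth target)
    depth: int = 100_000  # reads per technical replicate
    n_tech_reps: int = 2
    overdispersion: float | None = None  # Dirichlet-multinomial concentration
    n_experiments: int = 3
    n_bio_reps: int = 3
    lic_base: float = 1e-3  # baseline L-IC fraction per cell
    lic_sigma: float = 0.25  # lognormal spread of per-clone L-IC fraction
    n_hilic: int = 30
    hilic_from_resistant: int = 4  # resistant clones that are also high-L-IC
    hilic_multiplier: float = 8.0
    dose_ladder: tuple[int, ...] = (10_000, 1_000, 100, 10)
    mice_per_dose: int = 6
    engraftment_mice: int = 7
    engraftment_dose: int = 10_000

    def validate(self) -> None:
        if self.n_clones is not None and self.n_clones < 2:
            raise SimulationError("need at least 2 clones")
        if self.n_resistant < 0 or self.dirichlet_alpha <= 0:
            raise SimulationError("invalid population parameters")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dose_ladder"] = list(self.dose_ladder)
        return d


@dataclass
class RegimenSpec:
    """One treatment arm of the simulated study.

    ``kill_fraction`` is the expected bulk cell kill; clones labeled
    resistant survive it ``resistant_survival_multiplier`` times better
    (scaled so the bulk expectation still matches).  After the kill, clones
    regrow exponentially at their own rates times the regimen's growth
    factors; ``duration`` fixes the growth time for non-depleting regimens,
    otherwise growth runs until the culture reaches ``regrow_target``.
    """

    label: str
    kill_fraction: float = 0.0
    resistant_survival_multiplier: float = 1.0
    resistant_growth_factor: float = 1.0
    sensitive_growth_factor: float = 1.0
    #: probability that a clone's kill survivors resume proliferation in a
    #: given culture; clones that stay locked persist without growing and
    #: are diluted below detection by the regrowing ones.  Models the broad,
    #: stochastic regrowth suppression of hypomethylating-agent combination.
    clone_regrowth_prob: float = 1.0
    duration: float | None = None  # days; None = regrow to target
    regrow_target: float | None = None  # cells; None = population N0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kill_fraction < 1.0):
            raise SimulationError("kill fraction must be in [0, 1)")
        if self.resistant_survival_multiplier <= 0:
            raise SimulationError("survival multiplier must be positive")


def standard_regimens(config: SimConfig) -> dict[str, RegimenSpec]:
    """The emulated treatment arms.

    Kill fractions follow the printed bulk-elimination levels of the
    emulated study (Doxo ~99.56%, Doxo+Cyta ~99.96%, DAC combination
    ~99.90%; single-agent DAC has only a minor effect).  The DAC
    combination keeps the resistant clones' kill-survival advantage but
    suppresses their regrowth while mildly boosting the rest, which is what
    makes its relapses clonally unpredictable.
    """
    m = config.resistant_survival_multiplier
    return {
        "NT": RegimenSpec("NT", kill_fraction=0.0, duration=30.0),
        "DAC": RegimenSpec("DAC", kill_fraction=0.10, duration=30.0),
        "Doxo": RegimenSpec(
            "Doxo", kill_fraction=0.9956, resistant_survival_multiplier=m
        ),
        "Doxo+Cyta": RegimenSpec(
            "Doxo+Cyta", kill_fraction=0.9996, resistant_survival_multiplier=m
        ),
        "Doxo+Cyta+DAC": RegimenSpec(
            "Doxo+Cyta+DAC",
            kill_fraction=0.9990,
            resistant_survival_multiplier=m,
            resistant_growth_factor=0.15,
            clone_regrowth_prob=0.02,
        ),
    }


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


@dataclass
class ClonePopulation:
    """Simulator state: frequencies plus latent per-clone attributes."""

    clones: pd.DataFrame  # index barcode_id; frequency, growth_rate,
    #                       survival_weight, lic_fraction, resistant, hilic
    total_cells: float
    relapsed: bool = True  # False when a kill left no survivors
    trajectory: pd.DataFrame | None = None  # day-by-day total cells

    @property
    def frequencies(self) -> pd.Series:
        return self.clones["frequency"]

    @property
    def resistant_ids(self) -> frozenset[str]:
        return frozenset(self.clones.index[self.clones["resistant"]])

    @property
    def hilic_ids(self) -> frozenset[str]:
        return frozenset(self.clones.index[self.clones["hilic"]])

    @property
    def lic_frequency(self) -> float:
        """Population L-IC frequency per cell: sum(freq_i * lic_i)."""
        return float(
            (self.clones["frequency"] * self.clones["lic_fraction"]).sum()
        )


def generate_library(
    size: int = 2600, seed: int | np.random.Generator = 0, length: int = 20
) -> BarcodeLibrary:
    """Random DNA barcode library with pairwise-distinct 15-nt prefixes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < size:
        seq = "".join(rng.choice(bases, size=length))
        if seq[:15] not in seen:
            seen.add(seq[:15])
            seqs.append(seq)
    ids = [f"BC{i + 1:04d}" for i in range(size)]
    return BarcodeLibrary(tuple(ids), tuple(seqs))


def simulate_population(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    barcode_ids: Sequence[str] | None = None,
) -> ClonePopulation:
    """Draw a T0 clone population with planted ground-truth labels.

    Frequencies come from a symmetric Dirichlet; the planted resistant
    clones are the ``n_resistant`` clones starting at frequency rank
    ``resistant_rank_start`` (descending), i.e. sizeable but not dominant
    clones, and receive slower growth; most of them plus a random draw of
    others form the high-L-IC set with elevated L-IC fractions.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_clones if config.n_clones is not None else int(
        rng.integers(210, 331)
    )
    if n < 2:
        raise SimulationError("need at least 2 clones")
    if config.initial_distribution == "lognormal":
        freqs = rng.lognormal(0.0, config.lognormal_sigma, n)
    elif config.initial_distribution == "dirichlet":
        freqs = rng.dirichlet(np.full(n, config.dirichlet_alpha))
    else:
        raise SimulationError(
            f"unknown initial_distribution {config.initial_distribution!r}"
        )
    freqs = freqs / freqs.sum()
    if barcode_ids is None:
        ids = [f"BC{i + 1:04d}" for i in range(n)]
    else:
        if len(barcode_ids) != n:
            raise SimulationError("barcode_ids length != clone count")
        ids = [str(b) for b in barcode_ids]

    growth = rng.normal(config.growth_rate_mean, config.growth_rate_sd, n)
    growth = np.clip(growth, 0.05, None)
    if config.survival_noise_sd > 0:
        surv_weight = rng.lognormal(0.0, config.survival_noise_sd, n)
    else:
        surv_weight = np.ones(n)
    lic = config.lic_base * rng.lognormal(0.0, config.lic_sigma, n)

    order = np.argsort(-freqs, kind="stable")
    resistant = np.zeros(n, dtype=bool)
    k0 = min(config.resistant_rank_start, max(n - config.n_resistant, 0))
    resistant[order[k0 : k0 + config.n_resistant]] = True
    growth[resistant] *= config.resistant_growth_factor

    hilic = np.zeros(n, dtype=bool)
    res_idx = np.flatnonzero(resistant)
    n_from_res = min(config.hilic_from_resistant, len(res_idx))
    hilic[rng.choice(res_idx, size=n_from_res, replace=False)] = True
    others = np.flatnonzero(~resistant)
    n_other = min(max(config.n_hilic - n_from_res, 0), len(others))
    if n_other > 0:
        hilic[rng.choice(others, size=n_other, replace=False)] = True
    lic[hilic] *= config.hilic_multiplier

    clones = pd.DataFrame(
        {
            "frequency": freqs,
            "growth_rate": growth,
            "survival_weight": surv_weight,
            "lic_fraction": np.clip(lic, 0.0, 1.0),
            "resistant": resistant,
            "hilic": hilic,
        },
        index=pd.Index(ids, name="barcode_id"),
    )
    return ClonePopulation(clones=clones, total_cells=float(config.n0_cells))


# ---------------------------------------------------------------------------
# Treatment course
# ---------------------------------------------------------------------------


def _survival_probs(pop: ClonePopulation, regimen: RegimenSpec) -> np.ndarray:
    """Per-clone kill-survival probabilities, scaled to the bulk target."""
    f = pop.clones["frequency"].to_numpy()
    w = pop.clones["survival_weight"].to_numpy().copy()
    w[pop.clones["resistant"].to_numpy()] *= regimen.resistant_survival_multiplier
    target = 1.0 - regimen.kill_fraction
    scale = target / float((f * w).sum())
    return np.minimum(w * scale, 1.0)


def simulate_treatment_course(
    pop: ClonePopulation,
    regimen: RegimenSpec,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ClonePopulation:
    """One treatment-and-regrowth course for one culture replicate.

    Kill phase: per-clone binomial survival with probabilities scaled so
    the expected bulk kill matches the regimen target (no kill phase for
    kill_fraction 0, so an NT course with equal growth rates preserves
    frequencies exactly).  Regrow phase: deterministic exponential growth at
    clone rate x regimen growth factor until the culture reaches the
    regrowth target (or for ``duration`` days when fixed).  A course whose
    kill leaves no survivors is returned flagged ``relapsed=False``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    clones = pop.clones.copy()
    f = clones["frequency"].to_numpy(dtype=float)
    n0 = pop.total_cells

    if regimen.kill_fraction > 0.0:
        s = _survival_probs(pop, regimen)
        initial = np.rint(f * n0).astype(np.int64)
        survivors = rng.binomial(initial, s).astype(float)
    else:
        survivors = f * n0

    if survivors.sum() <= 0:
        clones["frequency"] = 0.0
        return ClonePopulation(
            clones=clones, total_cells=0.0, relapsed=False
        )

    g = clones["growth_rate"].to_numpy(dtype=float).copy()
    res = clones["resistant"].to_numpy()
    g[res] *= regimen.resistant_growth_factor
    g[~res] *= regimen.sensitive_growth_factor
    if regimen.clone_regrowth_prob < 1.0:
        locked = rng.random(len(g)) >= regimen.clone_regrowth_prob
        g[locked] = 0.0

    target = regimen.regrow_target if regimen.regrow_target is not None else n0
    if regimen.duration is None and (survivors[g > 0].sum() if (g > 0).any() else 0) <= 0:
        # nothing can regrow: flagged failed-relapse outcome
        total = float(survivors.sum())
        clones["frequency"] = survivors / total
        return ClonePopulation(clones=clones, total_cells=total, relapsed=False)

    def total_at(t: float) -> float:
        return float((survivors * np.exp(g * t)).sum())

    if regimen.duration is not None:
        t_final = regimen.duration
    else:
        if total_at(0.0) >= target:
            t_final = 0.0
        else:
            from scipy.optimize import brentq

            hi = 10.0
            while total_at(hi) < target and hi < 4000.0:
                hi *= 2.0
            t_final = float(brentq(lambda t: total_at(t) - target, 0.0, hi))

    days = np.arange(0.0, np.floor(t_final) + 1.0)
    traj = pd.DataFrame(
        {"day": days, "total_cells": [total_at(t) for t in days]}
    )
    final = survivors * np.exp(g * t_final)
    total = float(final.sum())
    clones["frequency"] = final / total
    return ClonePopulation(
        clones=clones, total_cells=total, relapsed=True, trajectory=traj
    )


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------


def simulate_sequencing(
    pop: ClonePopulation,
    depth: int = 100_000,
    n_tech_reps: int = 2,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    overdispersion: float | None = None,
) -> pd.DataFrame:
    """Barcode read counts for paired technical replicates of one sample.

    Each technical replicate is an independent multinomial draw of ``depth``
    reads over the clone frequencies; with ``overdispersion`` set, the
    multinomial probabilities of each replicate are themselves a Dirichlet
    draw with that concentration (Dirichlet-multinomial noise).
    """
    if depth <= 0:
        raise SimulationError("depth must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    f = pop.clones["frequency"].to_numpy(dtype=float)
    f = f / f.sum()
    cols = {}
    for rep in range(n_tech_reps):
        p = f
        if overdispersion is not None:
            positive = f > 0
            p = np.zeros_like(f)
            p[positive] = rng.dirichlet(f[positive] * overdispersion)
        cols[chr(ord("A") + rep)] = rng.multinomial(depth, p)
    out = pd.DataFrame(cols, index=pop.clones.index.copy())
    out.index.name = "barcode_id"
    return out


# ---------------------------------------------------------------------------
# Xenograft limiting dilution
# ---------------------------------------------------------------------------


def simulate_xenograft_lda(
    pop: ClonePopulation,
    dose_ladder: Sequence[int],
    mice_per_dose: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Limiting-dilution xenograft outcomes under the single-hit model.

    Each mouse at dose d receives, per clone, Poisson(d * freq_i * lic_i)
    leukemia-initiating cells; it scores positive iff it received at least
    one, and a clone is present in a mouse iff at least one of its L-ICs
    was injected.  Returns the (dose, tested, positive) design with
    realized outcomes and the mouse x barcode presence table (mouse dose in
    a ``dose`` column).
    """
    if len(dose_ladder) == 0:
        raise SimulationError("empty dose ladder")
    if rng is None:
        rng = np.random.default_rng(seed)
    f = pop.clones["frequency"].to_numpy(dtype=float)
    lic = pop.clones["lic_fraction"].to_numpy(dtype=float)
    rows = []
    presence = {}
    mouse_dose = {}
    for dose in dose_ladder:
        n_pos = 0
        for m in range(mice_per_dose):
            lam = dose * f * lic
            hits = rng.poisson(lam)
            positive = hits.sum() >= 1
            n_pos += int(positive)
            mouse_id = f"dose{dose}_m{m + 1}"
            presence[mouse_id] = (hits >= 1).astype(int)
            mouse_dose[mouse_id] = dose
        rows.append({"dose": dose, "tested": mice_per_dose, "positive": n_pos})
    design = pd.DataFrame(rows)
    engraft = pd.DataFrame(presence, index=pop.clones.index.copy()).T
    engraft.index.name = "mouse_id"
    engraft.insert(0, "dose", pd.Series(mouse_dose))
    return design, engraft


# ---------------------------------------------------------------------------
# Benchmark dataset
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkDataset:
    """A complete simulated study, in memory, with its ground truth."""

    config: SimConfig
    library: BarcodeLibrary
    population: ClonePopulation
    counts: pd.DataFrame  # barcode x sample raw read counts
    sheet: pd.DataFrame
    lda_design: pd.DataFrame
    engraftment: pd.DataFrame  # mouse x (dose + barcodes) presence
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_library(self.library, out / "library.tsv")
        write_counts(self.counts, out / "counts.tsv")
        write_sample_sheet(self.sheet, out / "sample_sheet.tsv")
        self.lda_design.to_csv(out / "lda_design.tsv", sep="\t", index=False)
        self.engraftment.to_csv(out / "engraftment.tsv", sep="\t")
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)


def make_benchmark_dataset(
    config: SimConfig | None = None,
    out_dir: str | Path | None = None,
    conditions: Sequence[str] = ("NT", "Doxo", "Doxo+Cyta", "Doxo+Cyta+DAC"),
) -> BenchmarkDataset:
    """Simulate the full multi-experiment study and (optionally) write it.

    Produces, under one master seed: a barcode library; one clone population
    shared by ``n_experiments`` independent experiments; per experiment a T0
    sample and ``n_bio_reps`` treatment courses per condition, each
    sequenced as paired technical replicates; plus a limiting-dilution
    design and a single-dose engraftment block on the T0 population.  The
    manifest records all planted ground truth.
    """
    config = config or SimConfig()
    config.validate()
    master = np.random.SeedSequence(config.seed)
    keys = [
        "library",
        "population",
        "courses",
        "sequencing",
        "xenograft",
        "engraftment",
    ]
    children = dict(zip(keys, master.spawn(len(keys))))
    rng_lib = np.random.default_rng(children["library"])
    rng_pop = np.random.default_rng(children["population"])
    rng_course = np.random.default_rng(children["courses"])
    rng_seq = np.random.default_rng(children["sequencing"])
    rng_xeno = np.random.default_rng(children["xenograft"])
    rng_eng = np.random.default_rng(children["engraftment"])

    library = generate_library(config.library_size, rng_lib)
    n = config.n_clones if config.n_clones is not None else int(
        rng_pop.integers(210, 331)
    )
    active_idx = np.sort(rng_pop.choice(config.library_size, size=n, replace=False))
    active_ids = [library.ids[i] for i in active_idx]
    cfg_fixed = config
    if config.n_clones is None:
        import dataclasses

        cfg_fixed = dataclasses.replace(config, n_clones=n)
    population = simulate_population(cfg_fixed, rng_pop, barcode_ids=active_ids)

    regimens = standard_regimens(config)
    col_counts: dict[str, np.ndarray] = {}
    sheet_rows: list[dict] = []

    def add_sample(pop_state, experiment, condition, bio_rep, timepoint):
        reads = simulate_sequencing(
            pop_state,
            depth=config.depth,
            n_tech_reps=config.n_tech_reps,
            rng=rng_seq,
            overdispersion=config.overdispersion,
        )
        for tech in reads.columns:
            sample_id = f"{experiment}_{condition}_{bio_rep}_{tech}".replace(
                "+", ""
            )
            col_counts[sample_id] = reads[tech].to_numpy()
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "cell_line": "SIM",
                    "condition": condition,
                    "experiment": experiment,
                    "bio_rep": bio_rep,
                    "tech_rep": tech,
                    "timepoint": timepoint,
                }
            )

    for e in range(1, config.n_experiments + 1):
        exp = f"E{e}"
        add_sample(population, exp, "NT", "r0", "T0")
        for condition in conditions:
            regimen = regimens[condition]
            for r in range(1, config.n_bio_reps + 1):
                course = simulate_treatment_course(
                    population, regimen, rng=rng_course
                )
                add_sample(course, exp, condition, f"r{r}", "Trelapse")

    counts = pd.DataFrame(col_counts, index=population.clones.index.copy())
    counts.index.name = "barcode_id"
    sheet = pd.DataFrame(sheet_rows)

    lda_design, _ = simulate_xenograft_lda(
        population, config.dose_ladder, config.mice_per_dose, rng=rng_xeno
    )
    _, engraftment = simulate_xenograft_lda(
        population,
        [config.engraftment_dose],
        config.engraftment_mice,
        rng=rng_eng,
    )

    manifest = {
        "config": cfg_fixed.to_dict(),
        "n_clones": int(len(population.clones)),
        "planted_resistant": sorted(population.resistant_ids),
        "planted_hilic": sorted(population.hilic_ids),
        "true_lic_frequency": population.lic_frequency,
    }
    dataset = BenchmarkDataset(
        config=cfg_fixed,
        library=library,
        population=population,
        counts=counts,
        sheet=sheet,
        lda_design=lda_design,
        engraftment=engraftment,
        manifest=manifest,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
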