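"""Synthetic enzyme-world generator with planted functional determinants.

Produces a protein family (star phylogeny from a random root), plants
class-enriched alignment columns, property shifts and an optional accessory
domain, draws an acid-tolerance flag from a logistic model over the planted
indicators, and simulates the downstream artifacts (plate assays with yield
tiers, DSF melt curves, per-residue property tables) so that every analysis
stage has a recoverable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, RESIDUE_CLASSES
from .seqio import SequenceRecord


@dataclass
class PlantedColumn:
    column: int
    residue_class: str
    enrichment: float  # carriage probability for acid-subfamily members
    weight: float = 2.0  # logistic weight toward acid tolerance
    baseline: float = 0.15  # carriage probability outside the acid subfamily


@dataclass
class SubfamilyConfig:
    """An acid-associated subfamily: a second root diverged at a fraction of
    columns, mirroring the clustered low-pH tolerance seen in real screens."""

    prior: float = 0.35  # probability an enzyme descends from the acid root
    divergence: float = 0.25  # fraction of columns substituted in the acid root


@dataclass
class PropertyShift:
    column: int
    property: str
    shift: float  # mean shift for acid-tolerant enzymes
    sd: float = 0.5


@dataclass
class AccessoryDomainConfig:
    attach_probability: float = 0.05
    attach_probability_subfamily: float = 0.45  # clade-associated, like CBM13
    logodds_boost: float = 2.5
    segment_length: int = 60
    substitution_rate: float = 0.05


@dataclass
class ConditionGrid:
    substrates: tuple[str, ...] = ("cryPow", "aFilm")
    temperatures: tuple[float, ...] = (40.0, 60.0)
    pHs: tuple[float, ...] = (4.5, 5.5, 6.5, 7.5)


@dataclass
class ActivityModel:
    bias_offset: float = -3.5  # shifts the acid-tolerance logistic threshold
    ph_width: float = 0.7  # gaussian width of the pH response
    acid_ph_optimum: float = 5.0
    neutral_ph_optimum: float = 7.2
    ph_opt_sd: float = 0.25
    tm_penalty_scale: float = 2.0  # softness of the Tm-temperature cutoff
    amax_log_mean: float = 3.0  # lognormal max specific activity, umol/mg
    amax_log_sd: float = 1.0
    dead_probability: float = 0.30  # enzymes with zero latent activity
    afilm_factor: float = 0.08
    tm_mean: float = 56.0
    tm_sd: float = 8.0


@dataclass
class AssayNoise:
    blank_a260: float = 0.08
    noise_sd: float = 0.01
    a260_per_umol: float = 34.0  # epsilon * path / volume = 17 / 0.5
    melt_noise_sd: float = 0.02  # fraction of curve amplitude
    melt_missing_probability: float = 0.05


@dataclass
class YieldModel:
    log_mean: float = 5.0  # lognormal of yield in ug (exp(5) ~ 148)
    log_sd: float = 0.8
    failure_probability: float = 0.35
    tier32_min_ug: float = 200.0
    tier8_min_ug: float = 90.0
    tier4_min_ug: float = 50.0  # == 0.1 mg/mL in a 0.5 mL well
    well_volume_ml: float = 0.5


@dataclass
class WorldConfig:
    n_enzymes: int = 212
    domain_length: int = 220
    substitution_rate: float = 0.30
    planted_conservation_columns: list[PlantedColumn] = field(
        default_factory=lambda: [
            PlantedColumn(30, "positive", 0.98, 3.0, baseline=0.12),
            PlantedColumn(85, "negative", 0.98, 3.0, baseline=0.12),
            PlantedColumn(140, "aromatic", 0.98, 3.0, baseline=0.12),
            PlantedColumn(25, "aliphatic", 0.98, 3.0, baseline=0.12),
            PlantedColumn(160, "proline_glycine", 0.98, 3.0, baseline=0.12),
            PlantedColumn(200, "polar", 0.98, 3.0, baseline=0.12),
        ]
    )
    subfamily: SubfamilyConfig = field(default_factory=SubfamilyConfig)
    planted_property_shifts: list[PropertyShift] = field(
        default_factory=lambda: [
            PropertyShift(60, "pKa", -0.37, 0.2),
            PropertyShift(110, "pKa", 1.5, 0.6),
            PropertyShift(170, "hydrophobicity", 1.0, 0.5),
            PropertyShift(95, "electrostatics", -0.8, 0.4),
            PropertyShift(45, "hydrophobicity", 0.8, 0.45),
            PropertyShift(130, "stickiness", 0.6, 0.35),
            PropertyShift(185, "circular_variance", -0.25, 0.15),
            PropertyShift(75, "electrostatics", -0.6, 0.4),
        ]
    )
    decoy_columns: list[int] = field(default_factory=lambda: [10, 50, 120, 190, 210])
    accessory_domain: AccessoryDomainConfig = field(default_factory=AccessoryDomainConfig)
    condition_grid: ConditionGrid = field(default_factory=ConditionGrid)
    activity_model: ActivityModel = field(default_factory=ActivityModel)
    assay_noise: AssayNoise = field(default_factory=AssayNoise)
    yield_model: YieldModel = field(default_factory=YieldModel)
    round_fractions: tuple[float, ...] = (0.2, 0.4, 0.4)  # DP / TEP / ESM
    seed: int = 0

    def validate(self) -> None:
        probs = [c.enrichment for c in self.planted_conservation_columns]
        probs += [c.baseline for c in self.planted_conservation_columns]
        probs += [self.subfamily.prior, self.subfamily.divergence]
        probs += [
            self.accessory_domain.attach_probability,
            self.accessory_domain.attach_probability_subfamily,
            self.activity_model.dead_probability,
            self.yield_model.failure_probability,
            self.assay_noise.melt_missing_probability,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        cols = [c.column for c in self.planted_conservation_columns]
        cols += [s.column for s in self.planted_property_shifts] + list(self.decoy_columns)
        if len(self.planted_conservation_columns) > self.domain_length or any(
            c >= self.domain_length for c in cols
        ):
            raise ValueError("planted columns must fit inside the domain")
        if self.assay_noise.noise_sd < 0:
            raise ValueError("absorbance noise sd must be nonnegative")
        grid = self.condition_grid
        if not (grid.substrates and grid.temperatures and grid.pHs):
            raise ValueError("condition grid must be nonempty")


@dataclass
class WorldTruth:
    """Ground truth of a generated world."""

    root: str
    sequences: list[SequenceRecord]
    true_alignment: dict[str, list[int]]  # per enzyme: residue index -> root column (-1 accessory)
    carries: pd.DataFrame  # enzyme x planted-column indicator
    subfamily_flag: dict[str, bool]
    accessory_flag: dict[str, bool]
    acid_tolerant_flag: dict[str, bool]
    acid_score: dict[str, float]
    true_tm: dict[str, float]
    ph_optimum: dict[str, float]
    amax: dict[str, float]
    yield_ug: dict[str, float]
    latent_activity: pd.DataFrame  # enzyme_id, substrate, pH, temperature, umol_per_mg
    planted_columns: list[PlantedColumn] = field(default_factory=list)
    planted_shifts: list[PropertyShift] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [r.id for r in self.sequences]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "root": self.root,
            "true_alignment": self.true_alignment,
            "subfamily_flag": self.subfamily_flag,
            "accessory_flag": self.accessory_flag,
            "acid_tolerant_flag": self.acid_tolerant_flag,
            "acid_score": self.acid_score,
            "true_tm": self.true_tm,
            "ph_optimum": self.ph_optimum,
            "amax": self.amax,
            "yield_ug": self.yield_ug,
            "planted_columns": [asdict(c) for c in self.planted_columns],
            "planted_shifts": [asdict(s) for s in self.planted_shifts],
        }
        Path(path).write_text(json.dumps(payload))


def _round_ids(n: int, fractions: Sequence[float]) -> list[str]:
    counts = [int(round(f / sum(fractions) * n)) for f in fractions]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmin(counts))] += 1
    ids = []
    for prefix, c in zip(("DP", "TEP", "ESM"), counts):
        ids.extend(f"{prefix}{i + 1:03d}" for i in range(c))
    return ids


def generate_world(config: WorldConfig) -> tuple[list[SequenceRecord], WorldTruth]:
    """Sample the enzyme family and all latent per-enzyme quantities."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_seq, r_plant, r_acid, r_act, r_yield, r_acc = rngs

    L = config.domain_length
    n = config.n_enzymes
    aa = np.array(list(AMINO_ACIDS))
    root = "".join(r_seq.choice(aa, size=L))
    acc_cfg = config.accessory_domain
    acc_root = "".join(r_acc.choice(aa, size=acc_cfg.segment_length))
    ids = _round_ids(n, config.round_fractions)

    planted = config.planted_conservation_columns
    planted_cols = {c.column for c in planted}
    # acid-associated subfamily: second root diverged at a fraction of columns
    subfam = r_plant.random(n) < config.subfamily.prior
    free_cols = np.array([j for j in range(L) if j not in planted_cols])
    n_div = int(round(config.subfamily.divergence * L))
    div_cols = r_plant.choice(free_cols, size=min(n_div, free_cols.size), replace=False)
    acid_root = list(root)
    for p in div_cols:
        choices = [c for c in AMINO_ACIDS if c != acid_root[p]]
        acid_root[p] = choices[r_plant.integers(len(choices))]
    acid_root = "".join(acid_root)
    carries = pd.DataFrame(
        {
            f"col{c.column}": r_plant.random(n)
            < np.where(subfam, c.enrichment, c.baseline)
            for c in planted
        },
        index=ids,
    )
    accessory = r_acc.random(n) < np.where(
        subfam, acc_cfg.attach_probability_subfamily, acc_cfg.attach_probability
    )

    sequences: list[SequenceRecord] = []
    true_alignment: dict[str, list[int]] = {}
    for i, eid in enumerate(ids):
        residues = list(acid_root if subfam[i] else root)
        n_sub = r_seq.poisson(config.substitution_rate * L)
        if n_sub > 0:
            pos = r_seq.choice(L, size=min(n_sub, L), replace=False)
            for p in pos:
                if p in planted_cols:
                    continue  # planted columns are set explicitly below
                choices = [c for c in AMINO_ACIDS if c != residues[p]]
                residues[p] = choices[r_seq.integers(len(choices))]
        for c in planted:
            members = sorted(RESIDUE_CLASSES[c.residue_class])
            if carries.iloc[i][f"col{c.column}"]:
                residues[c.column] = members[r_plant.integers(len(members))]
            else:
                non = [x for x in AMINO_ACIDS if x not in RESIDUE_CLASSES[c.residue_class]]
                residues[c.column] = non[r_plant.integers(len(non))]
        colmap = list(range(L))
        if accessory[i]:
            seg = list(acc_root)
            n_sub_a = r_acc.poisson(acc_cfg.substitution_rate * len(seg))
            if n_sub_a > 0:
                pos = r_acc.choice(len(seg), size=min(n_sub_a, len(seg)), replace=False)
                for p in pos:
                    choices = [c for c in AMINO_ACIDS if c != seg[p]]
                    seg[p] = choices[r_acc.integers(len(choices))]
            residues = residues + seg
            colmap = colmap + [-1] * len(seg)
        sequences.append(
            SequenceRecord(
                eid,
                "".join(residues),
                {"round": eid[: 2 if eid[2].isdigit() else 3], "accessory": bool(accessory[i])},
            )
        )
        true_alignment[eid] = colmap

    # acid tolerance: logistic of weighted planted indicators + noise, thresholded at 0
    weights = np.array([c.weight for c in planted])
    X = carries.to_numpy(float)
    prior = config.subfamily.prior
    expected = float(
        sum(
            c.weight * (prior * c.enrichment + (1 - prior) * c.baseline)
            for c in planted
        )
        + acc_cfg.logodds_boost
        * (
            prior * acc_cfg.attach_probability_subfamily
            + (1 - prior) * acc_cfg.attach_probability
        )
    )
    score = (
        X @ weights
        + acc_cfg.logodds_boost * accessory
        - expected
        + config.activity_model.bias_offset
        + r_acid.standard_normal(n)
    )
    flag = score > 0

    am = config.activity_model
    tm = np.clip(r_act.normal(am.tm_mean, am.tm_sd, n), 25.0, 90.0)
    ph_opt = np.where(
        flag,
        r_act.normal(am.acid_ph_optimum, am.ph_opt_sd, n),
        r_act.normal(am.neutral_ph_optimum, am.ph_opt_sd, n),
    )
    amax = np.exp(r_act.normal(am.amax_log_mean, am.amax_log_sd, n))
    dead = r_act.random(n) < am.dead_probability
    amax = np.where(dead, 0.0, amax)

    grid = config.condition_grid
    rows = []
    for i, eid in enumerate(ids):
        for sub in grid.substrates:
            sub_f = 1.0 if sub == "cryPow" else am.afilm_factor
            for temp in grid.temperatures:
                temp_f = 1.0 / (1.0 + np.exp((temp - tm[i]) / am.tm_penalty_scale))
                # activity plateaus below Tm
                temp_f = min(1.0, 2.0 * temp_f)
                for ph in grid.pHs:
                    ph_f = np.exp(-((ph - ph_opt[i]) ** 2) / (2.0 * am.ph_width**2))
                    rows.append(
                        {
                            "enzyme_id": eid,
                            "substrate": sub,
                            "pH": ph,
                            "temperature": temp,
                            "umol_per_mg": amax[i] * sub_f * temp_f * ph_f,
                        }
                    )
    latent = pd.DataFrame(rows)

    ym = config.yield_model
    failed = r_yield.random(n) < ym.failure_probability
    yields = np.exp(r_yield.normal(ym.log_mean, ym.log_sd, n))
    yields = np.where(failed, r_yield.uniform(0.0, ym.tier4_min_ug * 0.9, n), yields)

    truth = WorldTruth(
        root=root,
        sequences=sequences,
        true_alignment=true_alignment,
        carries=carries,
        subfamily_flag={eid: bool(subfam[i]) for i, eid in enumerate(ids)},
        accessory_flag={eid: bool(accessory[i]) for i, eid in enumerate(ids)},
        acid_tolerant_flag={eid: bool(flag[i]) for i, eid in enumerate(ids)},
        acid_score={eid: float(score[i]) for i, eid in enumerate(ids)},
        true_tm={eid: float(tm[i]) for i, eid in enumerate(ids)},
        ph_optimum={eid: float(ph_opt[i]) for i, eid in enumerate(ids)},
        amax={eid: float(amax[i]) for i, eid in enumerate(ids)},
        yield_ug={eid: float(yields[i]) for i, eid in enumerate(ids)},
        latent_activity=latent,
        planted_columns=list(planted),
        planted_shifts=list(config.planted_property_shifts),
    )
    return sequences, truth


def condition_tier(yield_ug: float, config: WorldConfig) -> int:
    """Condition-coverage tier from purified yield: 32, 8, 4 or 0 conditions."""
    ym = config.yield_model
    if yield_ug >= ym.tier32_min_ug:
        return 32
    if yield_ug >= ym.tier8_min_ug:
        return 8
    if yield_ug >= ym.tier4_min_ug:
        return 4
    return 0


def tier_conditions(tier: int, grid: ConditionGrid) -> list[tuple[str, float, float, int]]:
    """(substrate, pH, temperature, n_replicates) combinations for a yield tier."""
    if tier == 32:
        return [
            (s, ph, t, 2) for s in grid.substrates for t in grid.temperatures for ph in grid.pHs
        ]
    if tier == 8:
        return [("cryPow", ph, t, 1) for t in grid.temperatures for ph in grid.pHs]
    if tier == 4:
        return [("cryPow", ph, min(grid.temperatures), 1) for ph in grid.pHs]
    return []


def simulate_assay(truth: WorldTruth, config: WorldConfig) -> pd.DataFrame:
    """Well-level assay table: A260 = blank + coefficient x product + noise.

    Duplicate wells for the high-yield tier; condition coverage follows the
    simulated yield tier; enzymes below the purification threshold are absent.
    """
    config.validate()
    noise = config.assay_noise
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[6])
    latent = truth.latent_activity.set_index(["enzyme_id", "substrate", "pH", "temperature"])
    rows = []
    for rec in truth.sequences:
        eid = rec.id
        tier = condition_tier(truth.yield_ug[eid], config)
        for sub, ph, temp, reps in tier_conditions(tier, config.condition_grid):
            act = latent.loc[(eid, sub, ph, temp), "umol_per_mg"]
            umol = act * 0.005  # 5 ug loading
            for rep in range(1, reps + 1):
                eps = rng.normal(0.0, noise.noise_sd) if noise.noise_sd > 0 else 0.0
                a260 = noise.blank_a260 + noise.a260_per_umol * umol + eps
                rows.append(
                    {
                        "enzyme_id": eid,
                        "round": rec.round_label,
                        "substrate": sub,
                        "pH": ph,
                        "temperature": temp,
                        "replicate": rep,
                        "A260": max(0.0, a260),
                        "A280": max(0.0, 0.6 * (a260 - noise.blank_a260)),
                        "blank_A260": noise.blank_a260,
                    }
                )
    return pd.DataFrame(rows)


def simulate_melt_curves(
    truth: WorldTruth,
    config: WorldConfig,
    t_min: float = 25.0,
    t_max: float = 95.0,
    t_step: float = 0.5,
) -> pd.DataFrame:
    """Two-state sigmoid melt curves centered at true Tm, plus noise.

    A configurable fraction of enzymes yields a flat (no-transition) curve.
    """
    noise = config.assay_noise
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[7])
    temps = np.arange(t_min, t_max + t_step / 2, t_step)
    rows = []
    for rec in truth.sequences:
        eid = rec.id
        missing = rng.random() < noise.melt_missing_probability
        amplitude = 1000.0
        if missing:
            f = np.full_like(temps, 200.0)
        else:
            tm = truth.true_tm[eid]
            f = 200.0 + amplitude / (1.0 + np.exp(-(temps - tm) / 1.5))
        f = f + rng.normal(0.0, noise.melt_noise_sd * amplitude, temps.size)
        for t, y in zip(temps, f):
            rows.append({"enzyme_id": eid, "temperature": float(t), "fluorescence": float(y)})
    return pd.DataFrame(rows)


def expression_table(truth: WorldTruth, config: WorldConfig) -> pd.DataFrame:
    vol = config.yield_model.well_volume_ml
    rows = [
        {
            "enzyme_id": eid,
            "yield_ug": y,
            "concentration_mg_ml": y / 1000.0 / vol,
        }
        for eid, y in truth.yield_ug.items()
    ]
    return pd.DataFrame(rows)


PROPERTY_BASELINES = {
    "pKa": 6.0,
    "hydrophobicity": 0.0,
    "electrostatics": 0.0,
    "circular_variance": 0.5,
    "stickiness": 0.0,
}


def emit_property_tables(
    truth: WorldTruth,
    config: WorldConfig,
    decoy_sd: float = 0.5,
) -> pd.DataFrame:
    """Per-enzyme per-column property values; acid-tolerant enzymes are shifted
    by the configured mean at planted columns, decoy columns are unshifted.

    Long form: enzyme_id, column, property, value.
    """
    for s in config.planted_property_shifts:
        if s.property not in PROPERTY_BASELINES:
            raise ValueError(f"unknown property {s.property!r}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(9)[8])
    rows = []
    ids = truth.ids()
    flags = np.array([truth.acid_tolerant_flag[e] for e in ids], dtype=float)
    for s in config.planted_property_shifts:
        base = PROPERTY_BASELINES[s.property]
        vals = base + s.shift * flags + (
            rng.normal(0.0, s.sd, len(ids)) if s.sd > 0 else 0.0
        )
        for eid, v in zip(ids, vals):
            rows.append(
                {"enzyme_id": eid, "column": s.column, "property": s.property, "value": float(v)}
            )
    shifted = {(s.column, s.property) for s in config.planted_property_shifts}
    for col in config.decoy_columns:
        for prop, base in PROPERTY_BASELINES.items():
            if (col, prop) in shifted:
                continue
            vals = base + rng.normal(0.0, decoy_sd, len(ids))
            for eid, v in zip(ids, vals):
                rows.append(
                    {"enzyme_id": eid, "column": col, "property": prop, "value": float(v)}
                )
    return pd.DataFrame(rows)


def write_world(
    out_dir: str | Path, sequences: list[SequenceRecord], truth: WorldTruth, config: WorldConfig
) -> dict[str, Path]:
    """Write all synthetic artifacts as plain-text files; returns path map."""
    from .seqio import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": out / "sequences.fasta",
        "assay": out / "assay.csv",
        "melt": out / "melt_curves.csv",
        "expression": out / "expression.csv",
        "properties": out / "properties.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(sequences, paths["sequences"])
    simulate_assay(truth, config).to_csv(paths["assay"], index=False, float_format="%.6g")
    simulate_melt_curves(truth, config).to_csv(paths["melt"], index=False, float_format="%.6g")
    expression_table(truth, config).to_csv(paths["expression"], index=False, float_format="%.6g")
    emit_property_tables(truth, config).to_csv(
        paths["properties"], index=False, sep="\t", float_format="%.6g"
    )
    truth.to_json(paths["truth"])
    return paths
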