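"""Synthetic-world benchmark: determinant recovery and condition-model ordering.

One call evaluates a full screening loop on a generated world with known
ground truth: activity calling, group splitting, differential conservation,
per-position property statistics, factor counting, and the base-HMM /
tuned-HMM / supervised-model comparison under pooled cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import RESIDUE_CLASSES
from .assay import per_condition_table
from .groups import (
    conservation_factor_count,
    differential_conservation,
    factor_activity_correlation,
    position_property_test,
    split_groups,
)
from .hmm import build_profile, score_sequences, tune_hmm
from .msa import progressive_align
from .predictors import (
    auroc,
    condition_dataset,
    feature_matrix,
    make_folds,
    pooled_cv_predict,
)
from .seqio import Alignment, SequenceRecord
from .simulate import WorldConfig, emit_property_tables, generate_world, simulate_assay


@dataclass
class SeedBenchmark:
    seed: int
    n_condition_examples: int
    n_condition_active: int
    base_auroc: float
    tuned_auroc: float
    supervised_auroc: float
    balanced_accuracy: float
    conservation_recovered: int
    conservation_planted: int
    conservation_decoys_flagged: int
    conservation_decoy_columns: int
    property_recovered: int
    property_planted: int
    property_decoys_flagged: int
    property_decoy_pairs: int
    factor_spearman: float


def run_seed_benchmark(
    seed: int,
    n_enzymes: int = 200,
    condition: dict | None = None,
    cv_folds: int = 5,
) -> SeedBenchmark:
    """Generate a world, run the loop, and measure recovery against truth.

    The base profile is built from the Round-1 (DP prefix) actives — a
    condition-agnostic starting set — and tuned per CV fold by adding the
    training folds' condition-active enzymes.
    """
    if condition is None:
        condition = {"substrate": "cryPow", "pH": 4.5, "temperature": 40.0}
    cfg = WorldConfig(n_enzymes=n_enzymes, seed=seed)
    sequences, truth = generate_world(cfg)
    by_id = {r.id: r for r in sequences}
    per_cond = per_condition_table(simulate_assay(truth, cfg))

    # ---- group split and acid-flag recovery ---------------------------------
    split = split_groups(per_cond, low_ph=min(cfg.condition_grid.pHs))
    grouped = split.acid_group + split.neutral_group
    pred = np.array([eid in set(split.acid_group) for eid in grouped])
    true = np.array([truth.acid_tolerant_flag[eid] for eid in grouped])
    if true.any() and (~true).any():
        tpr = (pred & true).sum() / true.sum()
        tnr = (~pred & ~true).sum() / (~true).sum()
        balanced = float((tpr + tnr) / 2.0)
    else:
        balanced = float("nan")

    # ---- differential conservation on the catalytic domain ------------------
    L = cfg.domain_length
    domain_rows = [
        SequenceRecord(eid, by_id[eid].residues[:L]) for eid in grouped
    ]
    cons = differential_conservation(Alignment(domain_rows), split)
    flagged_cols = {f["column"] for f in cons}
    planted_cols = {c.column for c in cfg.planted_conservation_columns}
    cons_recovered = sum(
        1
        for c in cfg.planted_conservation_columns
        if any(
            f["column"] == c.column
            and f["class"] == c.residue_class
            and f["conserved_in"] == "acid"
            for f in cons
        )
    )
    decoy_flagged = len(flagged_cols - planted_cols)

    # ---- per-position property statistics -----------------------------------
    props = emit_property_tables(truth, cfg)
    factors = position_property_test(props, split)
    planted_pairs = {
        (s.column, s.property): s.shift
        for s in cfg.planted_property_shifts
        if s.shift != 0.0
    }
    prop_recovered = sum(
        1
        for f in factors
        if (f.column, f.property) in planted_pairs
        and np.sign(f.mean_difference) == np.sign(planted_pairs[(f.column, f.property)])
    )
    all_pairs = {(int(c), p) for c, p in props.groupby(["column", "property"]).groups}
    decoy_pairs = all_pairs - set(planted_pairs)
    prop_decoys = sum(1 for f in factors if (f.column, f.property) in decoy_pairs)

    cons_counts = conservation_factor_count(
        {r.id: r.residues for r in sequences}, cons
    )
    rho, _p, _table = factor_activity_correlation(
        props, factors, per_cond, condition, extra_counts=cons_counts, ids=grouped
    )

    # ---- base vs tuned vs supervised at the target condition -----------------
    recs, y, _act = condition_dataset(per_cond, sequences, condition)
    active_any = set(per_cond.loc[per_cond["active"], "enzyme_id"])
    base_ids = sorted(i for i in active_any if i.startswith("DP"))
    cond_active = sorted(r.id for r, label in zip(recs, y) if label)
    base_hmm = build_profile(progressive_align([by_id[i] for i in base_ids]))
    base_bits = score_sequences(base_hmm, recs)
    base_auc = auroc([base_bits[r.id] for r in recs], y)

    plan = make_folds([r.id for r in recs], cv_folds, seed)
    tuned_bits: dict[str, float] = {}
    for f in range(cv_folds):
        train_active = [by_id[i] for i in cond_active if plan.fold_of.get(i) != f]
        tuned = tune_hmm([by_id[i] for i in base_ids], train_active)
        held = [r for r in recs if plan.fold_of[r.id] == f]
        tuned_bits.update(score_sequences(tuned, held))
    tuned_auc = auroc([tuned_bits[r.id] for r in recs], y)

    X = feature_matrix(recs, hmm_bits=tuned_bits)
    preds = pooled_cv_predict(X, y, plan)
    sup_auc = auroc(preds, y)

    return SeedBenchmark(
        seed=seed,
        n_condition_examples=len(recs),
        n_condition_active=int(y.sum()),
        base_auroc=base_auc,
        tuned_auroc=tuned_auc,
        supervised_auroc=sup_auc,
        balanced_accuracy=balanced,
        conservation_recovered=cons_recovered,
        conservation_planted=len(cfg.planted_conservation_columns),
        conservation_decoys_flagged=decoy_flagged,
        conservation_decoy_columns=L - len(planted_cols),
        property_recovered=prop_recovered,
        property_planted=len(planted_pairs),
        property_decoys_flagged=prop_decoys,
        property_decoy_pairs=len(decoy_pairs),
        factor_spearman=rho,
    )
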