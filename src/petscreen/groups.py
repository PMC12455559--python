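"""Group comparison of low-pH-active vs neutral-only-active enzymes.

Differential conservation of physicochemical classes, per-position
Mann-Whitney tests on externally supplied property tables, factor counting,
reference-coordinate mapping and accessory-domain clustering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, spearmanr

from .alphabet import GAP, KYTE_DOOLITTLE, RESIDUE_CLASSES
from .seqio import Alignment, SequenceRecord, pairwise_identity


@dataclass
class GroupSplit:
    """Performance groups among active enzymes, split on activity at pH 4.5."""

    acid_group: list[str]
    neutral_group: list[str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.acid_group) & set(self.neutral_group):
            raise ValueError("groups must be disjoint")


def split_groups(per_condition: pd.DataFrame, low_ph: float = 4.5) -> GroupSplit:
    """Among active enzymes: acid group = active at low pH; neutral group =
    active but not at low pH; active enzymes never tested at low pH are
    excluded from both."""
    acid, neutral, excluded = [], [], []
    for eid, g in per_condition.groupby("enzyme_id", sort=True):
        if not g["active"].any():
            continue
        tested_low = (g["pH"] == low_ph).any()
        if not tested_low:
            excluded.append(eid)
        elif g.loc[g["pH"] == low_ph, "active"].any():
            acid.append(eid)
        else:
            neutral.append(eid)
    return GroupSplit(acid_group=acid, neutral_group=neutral, excluded=excluded)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U1, p). Exact p by enumeration over all group assignments for
    combined n <= 12 (ties handled through midranks); tie-corrected normal
    approximation with continuity correction otherwise. All-tied data gives
    p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if np.all(pooled == pooled[0]):
        return u1, 1.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    if n <= 12:
        stat_obs = abs(u1 - mu)
        count = 0
        total = 0
        base = ranks.sum()
        for combo in itertools.combinations(range(n), n1):
            r1 = sum(ranks[i] for i in combo)
            u = r1 - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= stat_obs - 1e-12:
                count += 1
            total += 1
        _ = base
        return u1, count / total
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return u1, float(res.pvalue)


@dataclass
class SignificantFactor:
    """A (column, property) pair with a significant group difference."""

    column: int
    property: str
    mean_acid: float
    mean_neutral: float
    mean_difference: float  # acid - neutral
    p_value: float
    reference_residue: int | None = None


def position_property_test(
    properties: pd.DataFrame,
    split: GroupSplit,
    alpha: float = 0.05,
    min_group_size: int = 3,
    bh_correction: bool = False,
) -> list[SignificantFactor]:
    """Two-sided Mann-Whitney per (column, property) between the groups.

    Positions with fewer than min_group_size values in either group are
    skipped. No multiple-testing correction by default (Benjamini-Hochberg
    available but off, matching the source procedure).
    """
    acid = set(split.acid_group)
    neutral = set(split.neutral_group)
    results = []
    for (col, prop), g in properties.groupby(["column", "property"], sort=True):
        xa = g.loc[g["enzyme_id"].isin(acid), "value"].to_numpy(float)
        xn = g.loc[g["enzyme_id"].isin(neutral), "value"].to_numpy(float)
        if len(xa) < min_group_size or len(xn) < min_group_size:
            continue
        _u, p = mann_whitney_u(xa, xn)
        results.append(
            SignificantFactor(
                column=int(col),
                property=str(prop),
                mean_acid=float(xa.mean()),
                mean_neutral=float(xn.mean()),
                mean_difference=float(xa.mean() - xn.mean()),
                p_value=float(p),
            )
        )
    if bh_correction and results:
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        prev = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            k = m - rank_i
            prev = min(prev, ps[idx] * m / k)
            adj[idx] = prev
        results = [r for r, q in zip(results, adj) if q < alpha]
    else:
        results = [r for r in results if r.p_value < alpha]
    return results


def differential_conservation(
    aln: Alignment,
    split: GroupSplit,
    class_scheme: dict[str, set] | None = None,
    hi: float = 0.9,
    lo: float = 0.5,
) -> list[dict]:
    """Columns where a physicochemical class is conserved (frequency >= hi) in
    one group but not the other (frequency <= lo); both directions reported."""
    scheme = RESIDUE_CLASSES if class_scheme is None else class_scheme
    ids = set(aln.ids())
    for eid in split.acid_group + split.neutral_group:
        if eid not in ids:
            raise ValueError(f"group member {eid!r} missing from alignment")
    rows_a = [aln.row(e).residues for e in split.acid_group]
    rows_n = [aln.row(e).residues for e in split.neutral_group]
    flagged = []
    for j in range(aln.n_columns):
        col_a = [r[j] for r in rows_a]
        col_n = [r[j] for r in rows_n]
        for cname, members in scheme.items():
            fa = sum(c in members for c in col_a) / len(col_a)
            fn = sum(c in members for c in col_n) / len(col_n)
            if fa >= hi and fn <= lo:
                flagged.append(
                    {
                        "column": j,
                        "class": cname,
                        "conserved_in": "acid",
                        "freq_acid": fa,
                        "freq_neutral": fn,
                    }
                )
            elif fn >= hi and fa <= lo:
                flagged.append(
                    {
                        "column": j,
                        "class": cname,
                        "conserved_in": "neutral",
                        "freq_acid": fa,
                        "freq_neutral": fn,
                    }
                )
    return flagged


def kyte_doolittle_profile(seq: str, window: int = 9) -> np.ndarray:
    """Windowed mean Kyte-Doolittle hydropathy; truncated windows at the ends.

    'X' and gaps contribute 0 to the window mean.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    vals = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])
    half = window // 2
    out = np.empty(len(seq))
    for i in range(len(seq)):
        lo_i = max(0, i - half)
        hi_i = min(len(seq), i + half + 1)
        out[i] = vals[lo_i:hi_i].mean()
    return out


@dataclass
class FactorProfile:
    """Per-enzyme exhibited-factor flags and their count."""

    enzyme_id: str
    exhibited: dict[tuple[int, str], bool]

    @property
    def count(self) -> int:
        return sum(self.exhibited.values())


def factor_profile(
    properties: pd.DataFrame,
    factors: list[SignificantFactor],
    enzyme_id: str,
) -> FactorProfile:
    """An enzyme exhibits a factor iff its value is strictly closer to the
    acid-group mean than to the neutral-group mean; missing values count as
    not exhibited."""
    if properties.empty:
        lookup: dict = {}
    else:
        sub = properties[properties["enzyme_id"] == enzyme_id]
        lookup = {
            (int(r["column"]), r["property"]): float(r["value"]) for _, r in sub.iterrows()
        }
    exhibited = {}
    for f in factors:
        key = (f.column, f.property)
        v = lookup.get(key)
        if v is None:
            exhibited[key] = False
        else:
            exhibited[key] = abs(v - f.mean_acid) < abs(v - f.mean_neutral)
    return FactorProfile(enzyme_id=enzyme_id, exhibited=exhibited)


def conservation_factor_count(
    residues_of: dict[str, str],
    conservation_flags: list[dict],
    class_scheme: dict[str, set] | None = None,
) -> dict[str, int]:
    """Per-enzyme count of acid-conserved positions the enzyme itself matches.

    conservation_flags is the differential_conservation output; an enzyme
    exhibits a flagged (column, class) when its own residue at that column
    belongs to the class conserved in the acid group.
    """
    scheme = RESIDUE_CLASSES if class_scheme is None else class_scheme
    counts = {eid: 0 for eid in residues_of}
    for flag in conservation_flags:
        if flag["conserved_in"] != "acid":
            continue
        members = scheme[flag["class"]]
        j = flag["column"]
        for eid, seq in residues_of.items():
            if j < len(seq) and seq[j] in members:
                counts[eid] += 1
    return counts


def factor_activity_correlation(
    properties: pd.DataFrame,
    factors: list[SignificantFactor],
    per_condition: pd.DataFrame,
    condition: dict | None = None,
    extra_counts: dict[str, int] | None = None,
    ids: list[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation between per-enzyme factor counts and measured
    activity at a fixed condition (default crystalline powder, pH 4.5, 40 C).

    extra_counts (e.g. conservation_factor_count output) is added to each
    enzyme's property-factor count before correlating. ids restricts the
    population (typically the grouped active enzymes the factors were
    defined on); default is every enzyme tested at the condition.
    """
    if condition is None:
        condition = {"substrate": "cryPow", "pH": 4.5, "temperature": 40.0}
    mask = np.ones(len(per_condition), dtype=bool)
    for key, val in condition.items():
        mask &= per_condition[key] == val
    acts = per_condition[mask].set_index("enzyme_id")["specific_activity"]
    if ids is not None:
        acts = acts[acts.index.isin(set(ids))]
    rows = []
    for eid in acts.index:
        prof = factor_profile(properties, factors, eid)
        count = prof.count + (extra_counts.get(eid, 0) if extra_counts else 0)
        rows.append({"enzyme_id": eid, "factor_count": count, "activity": float(acts[eid])})
    table = pd.DataFrame(rows)
    if len(table) < 3 or table["factor_count"].nunique() < 2:
        return float("nan"), float("nan"), table
    rho, p = spearmanr(table["factor_count"], table["activity"])
    return float(rho), float(p), table


def map_to_reference(aln: Alignment, reference_id: str) -> dict[int, int | None]:
    """Alignment column (0-based) -> 1-based residue number of the reference
    row; None where the reference is gapped."""
    ref = aln.row(reference_id)
    mapping: dict[int, int | None] = {}
    res_no = 0
    for j, c in enumerate(ref.residues):
        if c == GAP:
            mapping[j] = None
        else:
            res_no += 1
            mapping[j] = res_no
    return mapping


def annotate_reference(
    factors: list[SignificantFactor], aln: Alignment, reference_id: str
) -> list[SignificantFactor]:
    mapping = map_to_reference(aln, reference_id)
    for f in factors:
        f.reference_residue = mapping.get(f.column)
    return factors


@dataclass
class AccessoryCluster:
    members: list[str]
    hit_rate_low_ph: float | None


def extract_accessory_segments(
    records: list[SequenceRecord], hmm, min_length: int = 40
) -> dict[str, str]:
    """Residues outside each sequence's profile-matched span, if long enough."""
    segments: dict[str, str] = {}
    for rec in records:
        span = hmm.matched_span(rec)
        if span is None:
            continue
        start, end = span
        tail = rec.residues[end:]
        head = rec.residues[:start]
        seg = max(head, tail, key=len)
        if len(seg) >= min_length:
            segments[rec.id] = seg
    return segments


def cluster_accessory_domains(
    records: list[SequenceRecord],
    hmm,
    active_at_low_ph: dict[str, bool],
    identity_threshold: float = 0.35,
    min_length: int = 40,
) -> list[AccessoryCluster]:
    """Single-linkage clusters of accessory segments at an identity threshold,
    each annotated with its members' low-pH hit rate."""
    segments = extract_accessory_segments(records, hmm, min_length)
    ids = sorted(segments)
    if not ids:
        return []
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in itertools.combinations(ids, 2):
        ident = pairwise_identity(
            SequenceRecord(a, segments[a]), SequenceRecord(b, segments[b])
        )
        if ident >= identity_threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    out = []
    for members in clusters.values():
        known = [active_at_low_ph[m] for m in members if m in active_at_low_ph]
        rate = float(np.mean(known)) if known else None
        out.append(AccessoryCluster(members=sorted(members), hit_rate_low_ph=rate))
    out.sort(key=lambda c: (-len(c.members), c.members[0]))
    return out
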