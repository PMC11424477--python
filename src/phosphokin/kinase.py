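"""Kinase activity inference from site-group log2 fold changes.

A kinase's activity shift between two conditions is scored by comparing the
mean log2 fold change of its detected substrate site groups against the
overall fold-change distribution:

    Z = (M - mu) / se,   se = s / sqrt(m)

where M is the substrate mean, mu and s the mean and sample SD of *all*
detected site-group fold changes in the contrast, and m the number of
detected substrates. P values are two-tailed under a standard-normal null,
P = 2 * (1 - Phi(|Z|)); significance uses unadjusted P by default, with BH
across kinases available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ParameterError, ParseError
from .sites import PHOSPHO_RESIDUES, group_key_sites, make_site_key
from .site_quant import adjust_bh

__all__ = [
    "KinaseSubstrateMap",
    "load_kinase_substrate_map",
    "match_substrates",
    "infer_kinase_activities",
    "sitewise_ztest",
    "contrast_activity_profiles",
]

KINASE_RESULT_COLUMNS = ["kinase", "m", "M", "mu", "s", "se", "Z", "pvalue", "significant", "reason"]

_TINY = float(np.finfo(float).tiny)


@dataclass
class KinaseSubstrateMap:
    """Kinase -> set of phosphosite keys (substrate network)."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for kinase, sites in self.entries.items():
            sites = frozenset(sites)
            if not sites:
                raise ParameterError(f"kinase {kinase!r} has an empty substrate set")
            clean[kinase] = sites
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, kinase) -> bool:
        return kinase in self.entries

    @property
    def kinases(self) -> list[str]:
        return sorted(self.entries)

    def all_sites(self) -> frozenset[str]:
        out: set[str] = set()
        for sites in self.entries.values():
            out |= sites
        return frozenset(out)

    def overlap_rate(self) -> float:
        """Fraction of substrate sites claimed by more than one kinase."""
        if not self.entries:
            return 0.0
        counts: dict[str, int] = {}
        for sites in self.entries.values():
            for s in sites:
                counts[s] = counts.get(s, 0) + 1
        shared = sum(1 for v in counts.values() if v > 1)
        return shared / len(counts)

    def to_tsv(self, path) -> None:
        from .sites import parse_site_key

        rows = []
        for kinase in self.kinases:
            for key in sorted(self.entries[kinase]):
                protein, res, pos = parse_site_key(key)
                rows.append((kinase, protein, res, pos))
        pd.DataFrame(rows, columns=["kinase", "substrate_protein", "residue", "position"]).to_csv(
            Path(path), sep="\t", index=False
        )


def load_kinase_substrate_map(path) -> KinaseSubstrateMap:
    """Parse an OmniPath-style kinase-substrate TSV.

    Expected header: kinase, substrate_protein, residue, position. Exact
    duplicate rows collapse to one substrate entry; malformed rows raise a
    ParseError naming the offending line (1-based, counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["kinase", "substrate_protein", "residue", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: kinase-substrate table missing columns {missing}")
    entries: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if any(pd.isna(v) or str(v).strip() == "" for v in row):
            raise ParseError(f"{path}: line {i}: missing field")
        residue = str(row.residue).strip()
        if residue not in PHOSPHO_RESIDUES:
            raise ParseError(f"{path}: line {i}: residue {residue!r} not in S/T/Y")
        try:
            position = int(str(row.position).strip())
        except ValueError:
            raise ParseError(f"{path}: line {i}: position {row.position!r} is not an integer") from None
        if position < 1:
            raise ParseError(f"{path}: line {i}: position must be positive")
        key = make_site_key(str(row.substrate_protein).strip(), residue, position)
        entries.setdefault(str(row.kinase).strip(), set()).add(key)
    return KinaseSubstrateMap({k: frozenset(v) for k, v in entries.items()})


def match_substrates(
    ksmap: KinaseSubstrateMap,
    detected,
    rule: str = "any-site",
) -> dict[str, frozenset[str]]:
    """Match detected site groups to each kinase's substrate set.

    Under the default ``"any-site"`` rule a group matches a kinase if any
    site in the group's set is a substrate of that kinase; under
    ``"exact-singleton"`` only single-site groups whose one site is a
    substrate match. Each matched group counts once per kinase; a group may
    match several kinases.
    """
    if rule not in ("any-site", "exact-singleton"):
        raise ParameterError(f"match_substrates: unknown rule {rule!r}")
    detected = list(detected)
    group_sites = {g: group_key_sites(g) for g in detected}
    out = {}
    for kinase, substrates in ksmap.entries.items():
        if rule == "any-site":
            matched = {g for g, sites in group_sites.items() if any(s in substrates for s in sites)}
        else:
            matched = {g for g, sites in group_sites.items() if len(sites) == 1 and sites[0] in substrates}
        out[kinase] = frozenset(matched)
    return out


def infer_kinase_activities(
    fold_changes,
    ksmap: KinaseSubstrateMap,
    min_substrates: int = 3,
    alpha: float = 0.05,
    rule: str = "any-site",
    adjust: bool = False,
) -> pd.DataFrame:
    """Score every kinase's activity shift from site-group fold changes.

    ``fold_changes`` maps site-group key -> log2FC (Series or dict); groups
    with missing fold changes are ignored. mu and s (sample SD, ddof=1) are
    computed once over all detected groups; per kinase with at least
    ``min_substrates`` matched groups, M is the substrate mean and
    Z = (M - mu) / (s / sqrt(m)) with a two-tailed normal P. Kinases below
    the substrate cutoff are still reported, with a reason code and missing
    statistics. ``adjust=True`` additionally applies BH across tested
    kinases and flags significance on the adjusted P.
    """
    fc = pd.Series(fold_changes, dtype=float).dropna()
    if len(fc) < 2:
        raise ParameterError("infer_kinase_activities: need at least 2 fold changes to estimate s")
    if min_substrates < 1:
        raise ParameterError("infer_kinase_activities: min_substrates must be >= 1")
    mu = float(fc.mean())
    s = float(fc.std(ddof=1))
    if s == 0:
        raise ParameterError("infer_kinase_activities: all fold changes identical; s = 0, statistic undefined")

    matches = match_substrates(ksmap, fc.index, rule=rule)
    records = []
    for kinase in ksmap.kinases:
        groups = matches[kinase]
        m = len(groups)
        rec = {
            "kinase": kinase, "m": m, "M": np.nan, "mu": mu, "s": s,
            "se": np.nan, "Z": np.nan, "pvalue": np.nan,
            "significant": False, "reason": "",
        }
        if m >= 1:
            rec["M"] = float(fc[sorted(groups)].mean())
        if m < min_substrates:
            rec["reason"] = "insufficient_substrates"
        else:
            se = s / np.sqrt(m)
            z = (rec["M"] - mu) / se
            rec.update(se=se, Z=z, pvalue=max(2.0 * float(norm.sf(abs(z))), _TINY))
        records.append(rec)
    result = pd.DataFrame.from_records(records, columns=KINASE_RESULT_COLUMNS)
    tested = result["pvalue"].notna()
    if adjust and tested.any():
        result.loc[tested, "adj_pvalue"] = adjust_bh(result.loc[tested, "pvalue"].to_numpy())
        result.loc[tested, "significant"] = result.loc[tested, "adj_pvalue"] < alpha
    else:
        result.loc[tested, "significant"] = result.loc[tested, "pvalue"] < alpha
    return result


def sitewise_ztest(fold_changes) -> pd.Series:
    """Two-tailed z-test of each site group against the overall distribution.

    z = (x - mu) / s with mu, s the mean and sample SD of all fold changes;
    P = 2 * (1 - Phi(|z|)).
    """
    fc = pd.Series(fold_changes, dtype=float).dropna()
    if len(fc) < 2:
        raise ParameterError("sitewise_ztest: need at least 2 fold changes")
    s = float(fc.std(ddof=1))
    if s == 0:
        raise ParameterError("sitewise_ztest: zero spread in fold changes; z undefined")
    z = (fc - fc.mean()) / s
    p = 2.0 * norm.sf(np.abs(z))
    return pd.Series(np.maximum(p, _TINY), index=fc.index, name="pvalue")


def contrast_activity_profiles(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full outer join of two kinase-activity tables with a concordance class.

    Classes: ``concordant-up`` / ``concordant-down`` (both significant, same
    sign), ``discordant`` (both significant, opposite signs), ``A-only`` /
    ``B-only`` (significant in one dataset only, including kinases absent or
    untested in the other), ``both-null`` otherwise.
    """
    a = results_a.set_index("kinase")[["Z", "pvalue"]].rename(columns={"Z": "Z_A", "pvalue": "P_A"})
    b = results_b.set_index("kinase")[["Z", "pvalue"]].rename(columns={"Z": "Z_B", "pvalue": "P_B"})
    joined = a.join(b, how="outer")

    def classify(row):
        sig_a = bool(row["P_A"] < alpha) if pd.notna(row["P_A"]) else False
        sig_b = bool(row["P_B"] < alpha) if pd.notna(row["P_B"]) else False
        if sig_a and sig_b:
            if np.sign(row["Z_A"]) == np.sign(row["Z_B"]):
                return "concordant-up" if row["Z_A"] > 0 else "concordant-down"
            return "discordant"
        if sig_a:
            return "A-only"
        if sig_b:
            return "B-only"
        return "both-null"

    joined["class"] = joined.apply(classify, axis=1)
    joined.index.name = "kinase"
    return joined.sort_index().reset_index()
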