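"""Downstream report statistics: tRNA amino-acid clusters, per-class DE
tables, set-overlap summaries, and GO annotation counts with hypergeometric
enrichment."""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .seqio import Feature
from .stats import CountMatrix, bh_adjust, condition_tpm, percent_change, \
    round_half_up

logger = logging.getLogger(__name__)


def aggregate_trna_by_aa(cm: CountMatrix, features: list[Feature],
                         condition_a: str = "control",
                         condition_b: str = "heat",
                         highlight_threshold: float = 30.0) -> pd.DataFrame:
    """Amino-acid-clustered tRNA tpm per condition with percent change.

    Per-library tpm is computed on the full count matrix, averaged over each
    condition's replicates, then summed over the member tRNAs of each amino
    acid.  Clusters whose absolute percent change exceeds the highlight
    threshold are flagged.  tRNAs lacking an amino-acid attribute go to an
    "unknown" bucket with a warning.
    """
    aa_of: dict[str, str] = {}
    members: dict[str, list[str]] = defaultdict(list)
    for f in features:
        if f.ftype != "tRNA" or f.feature_id is None:
            continue
        aa = f.attributes.get("amino_acid")
        if aa is None:
            logger.warning("tRNA %s lacks an amino_acid attribute", f.feature_id)
            aa = "unknown"
        aa_of[f.feature_id] = aa
        members[aa].append(f.feature_id)

    tpm_a = condition_tpm(cm, condition_a)
    tpm_b = condition_tpm(cm, condition_b)
    rows = []
    for aa in sorted(members):
        ids = [t for t in members[aa] if t in cm.counts.index]
        ca = float(tpm_a.reindex(ids).fillna(0).sum())
        cb = float(tpm_b.reindex(ids).fillna(0).sum())
        change = percent_change(ca, cb) if max(ca, cb) > 0 else 0.0
        rows.append({
            "amino_acid": aa, "tpm_control": ca, "tpm_heat": cb,
            "percent_change": round_half_up(change, 2),
            "highlighted": abs(change) > highlight_threshold,
            "n_members": len(members[aa]),
            "members": ",".join(sorted(members[aa])),
        })
    return pd.DataFrame(rows)


def _render_log2fc(value: float) -> str:
    if value == float("inf"):
        return "inf"
    if value == float("-inf"):
        return "-inf"
    return f"{round_half_up(value, 2):.2f}"


def de_report(de: pd.DataFrame, feature_group: dict[str, str] | None = None,
              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-class significant-DE report with 2-dp log2fc and inf rendering.

    Rows are filtered to fdr < threshold; ``feature_group`` optionally maps
    feature id to a grouping label (amino acid, snoRNA family, ...).
    """
    sig = de[de["fdr"] < fdr_threshold].copy()
    sig["log2fc_rendered"] = sig["log2fc"].map(_render_log2fc)
    sig["significant"] = True
    if feature_group:
        sig["group"] = sig["id"].map(lambda i: feature_group.get(i, ""))
        sig = sig.sort_values(["group", "id"]).reset_index(drop=True)
    else:
        sig = sig.sort_values("id").reset_index(drop=True)
    return sig


def venn_summary(sets: dict[str, set]) -> dict[str, int]:
    """Exclusive-region counts for every non-empty combination of sets.

    Region keys join the member set names with "&"; each element of the
    union is counted in exactly one region (the sets it belongs to and no
    other).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo),
                                set())
            out["&".join(combo)] = len(inside - outside)
    return out


def go_annotate(targets_known: set[str], targets_novel: set[str],
                go_table: pd.DataFrame) -> pd.DataFrame:
    """Count predicted targets per GO category, split by known/novel miRNAs.

    ``go_table`` maps gene -> GO id/description (columns: gene_id, go_id,
    go_description).  Targets absent from the table are counted in an
    "unannotated" row.
    """
    required = {"gene_id", "go_id", "go_description"}
    if not required <= set(go_table.columns):
        raise ValueError(f"GO table needs columns {sorted(required)}")
    gene_go: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for row in go_table.itertuples(index=False):
        gene_go[row.gene_id].append((row.go_id, row.go_description))

    counts: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    unannotated = [0, 0]
    for slot, targets in ((0, targets_known), (1, targets_novel)):
        for g in targets:
            if g not in gene_go:
                unannotated[slot] += 1
                continue
            for go_id, desc in gene_go[g]:
                counts[(go_id, desc)][slot] += 1
    rows = [{"go_id": go_id, "description": desc,
             "n_targets_known": c[0], "n_targets_novel": c[1]}
            for (go_id, desc), c in sorted(counts.items())]
    if any(unannotated):
        rows.append({"go_id": "unannotated", "description": "not in GO table",
                     "n_targets_known": unannotated[0],
                     "n_targets_novel": unannotated[1]})
    return pd.DataFrame(rows, columns=["go_id", "description",
                                       "n_targets_known", "n_targets_novel"])


def go_enrich(n_targets_in_category: int, n_targets: int,
              n_background_in_category: int, n_background: int) -> float:
    """Hypergeometric upper-tail enrichment p-value.

    Probability of drawing at least the observed number of in-category genes
    when sampling ``n_targets`` genes from a background of ``n_background``
    containing ``n_background_in_category`` category members.
    """
    if n_targets_in_category > n_targets:
        raise ValueError("category count exceeds target-set size")
    if n_background_in_category > n_background:
        raise ValueError("category count exceeds background size")
    return float(hypergeom.sf(n_targets_in_category - 1, n_background,
                              n_background_in_category, n_targets))


def go_enrichment_table(target_sets: dict[str, set[str]],
                        go_table: pd.DataFrame,
                        background: set[str]) -> pd.DataFrame:
    """Per-category enrichment for each target set, BH-adjusted within set."""
    gene_cats: dict[str, set[str]] = defaultdict(set)
    desc: dict[str, str] = {}
    for row in go_table.itertuples(index=False):
        gene_cats[row.gene_id].add(row.go_id)
        desc[row.go_id] = row.go_description
    cat_bg = defaultdict(int)
    for g in background:
        for c in gene_cats.get(g, ()):
            cat_bg[c] += 1

    frames = []
    for set_name, targets in sorted(target_sets.items()):
        targets = targets & background
        cat_t = defaultdict(int)
        for g in targets:
            for c in gene_cats.get(g, ()):
                cat_t[c] += 1
        rows = []
        for c in sorted(cat_t):
            p = go_enrich(cat_t[c], len(targets), cat_bg[c], len(background))
            rows.append({"set": set_name, "go_id": c,
                         "description": desc.get(c, ""),
                         "n_in_category": cat_t[c],
                         "n_background_in_category": cat_bg[c], "p": p})
        df = pd.DataFrame(rows)
        if not df.empty:
            df["fdr"] = bh_adjust(df["p"].to_numpy())
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["set", "go_id", "description",
                                     "n_in_category",
                                     "n_background_in_category", "p", "fdr"])
    return pd.concat(frames, ignore_index=True)
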