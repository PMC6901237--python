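"""The 42 per-genome mutational features.

Each cancer genome is described by 29 general features — mutational load
(n_ssm, n_sim), the share of indels among all mutations, the distribution of
SSMs over the six pyrimidine-collapsed subtypes, of 1 bp SIMs over the four
strand-collapsed subtypes, and, per 1 bp SIM subtype, the distribution over
the four homopolymer context classes — plus 13 recurrence features computed
against the full-cohort recurrence index (overall recurrent-SSM %, overall
recurrent-SIM %, % of recurrent mutations that are SIMs, and per-subtype
recurrent percentages).  Homopolymer context is deliberately absent from the
recurrence features.  Except for the two absolute counts, every feature is a
percentage; degenerate 0/0 denominators resolve to 0 so the matrix is always
complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .io_context import HOMOPOLYMER_CATEGORIES, SIM_SUBTYPES, SSM_SUBTYPES
from .recurrence import RecurrenceIndex, annotate_recurrence, build_pancancer_index

log = logging.getLogger(__name__)


def _general_names() -> list[str]:
    names = ["n_ssm", "n_sim", "pct_sim_of_total"]
    names += [f"pct_ssm[{s}]" for s in SSM_SUBTYPES]
    names += [f"pct_sim[{s}]" for s in SIM_SUBTYPES]
    names += [
        f"pct_sim[{s}][{c}]" for s in SIM_SUBTYPES for c in HOMOPOLYMER_CATEGORIES
    ]
    return names


def _recurrence_names() -> list[str]:
    names = ["pct_recurrent_ssm", "pct_recurrent_sim", "pct_recurrent_that_are_sim"]
    names += [f"pct_recurrent_ssm[{s}]" for s in SSM_SUBTYPES]
    names += [f"pct_recurrent_sim[{s}]" for s in SIM_SUBTYPES]
    return names


GENERAL_FEATURES: tuple[str, ...] = tuple(_general_names())  # 29
RECURRENCE_FEATURES: tuple[str, ...] = tuple(_recurrence_names())  # 13
FEATURE_NAMES: tuple[str, ...] = GENERAL_FEATURES + RECURRENCE_FEATURES  # 42


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else 0.0


def compute_general_features(sample_mutations: pd.DataFrame) -> dict[str, float]:
    """The 29 load/subtype/context features of one sample.

    SIM-subtype and homopolymer percentages are computed over 1 bp SIMs only;
    multi-bp SIMs contribute to ``n_sim`` and ``pct_sim_of_total`` alone.
    """
    df = sample_mutations
    is_ssm = df["kind"] == "SSM"
    is_sim = df["kind"] == "SIM"
    n_ssm, n_sim = int(is_ssm.sum()), int(is_sim.sum())
    out = {
        "n_ssm": float(n_ssm),
        "n_sim": float(n_sim),
        "pct_sim_of_total": _pct(n_sim, n_ssm + n_sim),
    }
    ssm_counts = df.loc[is_ssm, "subtype"].value_counts()
    for s in SSM_SUBTYPES:
        out[f"pct_ssm[{s}]"] = _pct(ssm_counts.get(s, 0), n_ssm)
    sim1 = df[is_sim & df["is_1bp"]]
    n_sim1 = len(sim1)
    sub_counts = sim1["subtype"].value_counts()
    for s in SIM_SUBTYPES:
        out[f"pct_sim[{s}]"] = _pct(sub_counts.get(s, 0), n_sim1)
    ctx_counts = sim1.groupby(["subtype", "homopolymer_category"]).size()
    for s in SIM_SUBTYPES:
        den = sub_counts.get(s, 0)
        for c in HOMOPOLYMER_CATEGORIES:
            out[f"pct_sim[{s}][{c}]"] = _pct(ctx_counts.get((s, c), 0), den)
    return out


def compute_recurrence_features(
    sample_mutations: pd.DataFrame, index: RecurrenceIndex
) -> dict[str, float]:
    """The 13 recurrence features of one sample against a cohort index."""
    ann = annotate_recurrence(sample_mutations, index)
    is_ssm = ann["kind"] == "SSM"
    is_sim = ann["kind"] == "SIM"
    rec = ann["recurrent"]
    out = {
        "pct_recurrent_ssm": _pct(int((is_ssm & rec).sum()), int(is_ssm.sum())),
        "pct_recurrent_sim": _pct(int((is_sim & rec).sum()), int(is_sim.sum())),
        "pct_recurrent_that_are_sim": _pct(int((is_sim & rec).sum()), int(rec.sum())),
    }
    for s in SSM_SUBTYPES:
        m = is_ssm & (ann["subtype"] == s)
        out[f"pct_recurrent_ssm[{s}]"] = _pct(int((m & rec).sum()), int(m.sum()))
    for s in SIM_SUBTYPES:
        m = is_sim & ann["is_1bp"] & (ann["subtype"] == s)
        out[f"pct_recurrent_sim[{s}]"] = _pct(int((m & rec).sum()), int(m.sum()))
    return out


@dataclass
class FeatureMatrix:
    """Samples x 42 feature table with optional per-sample metadata."""

    data: pd.DataFrame  # index: sample_id; columns: FEATURE_NAMES
    metadata: Optional[pd.Series] = None  # sample_id -> tumour-type / group label

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def general_only(self) -> "FeatureMatrix":
        """The 29 general features (recurrence features dropped)."""
        return FeatureMatrix(self.data[list(GENERAL_FEATURES)].copy(), self.metadata)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def assemble_feature_matrix(
    mutations: pd.DataFrame,
    sample_ids: Optional[list[str]] = None,
    index: Optional[RecurrenceIndex] = None,
    metadata: Optional[pd.Series] = None,
) -> FeatureMatrix:
    """Compute the full 42-feature matrix for a cohort.

    Row order follows ``sample_ids`` when given (manifest order), otherwise
    first appearance in the table.  The recurrence index defaults to the
    pan-cancer index over ``mutations`` itself.
    """
    if index is None:
        index = build_pancancer_index(mutations)
    if sample_ids is None:
        sample_ids = list(dict.fromkeys(mutations["sample_id"]))
    ann = annotate_recurrence(mutations, index)
    groups = dict(list(ann.groupby("sample_id", sort=False)))
    empty = ann.iloc[0:0]
    rows = []
    for sid in sample_ids:
        sample = groups.get(sid, empty)
        if sample.empty:
            log.warning("sample %s has no mutations; feature row is all zeros", sid)
        feats = compute_general_features(sample)
        feats.update(_recurrence_from_annotated(sample))
        rows.append(feats)
    data = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    data = data[list(FEATURE_NAMES)]
    return FeatureMatrix(data, metadata)


def _recurrence_from_annotated(ann: pd.DataFrame) -> dict[str, float]:
    # Same arithmetic as compute_recurrence_features, on a pre-annotated frame.
    if "recurrent" not in ann:
        raise ValueError("expected an annotated mutation table")
    is_ssm = ann["kind"] == "SSM"
    is_sim = ann["kind"] == "SIM"
    rec = ann["recurrent"] if len(ann) else pd.Series(dtype=bool)
    out = {
        "pct_recurrent_ssm": _pct(int((is_ssm & rec).sum()), int(is_ssm.sum())),
        "pct_recurrent_sim": _pct(int((is_sim & rec).sum()), int(is_sim.sum())),
        "pct_recurrent_that_are_sim": _pct(int((is_sim & rec).sum()), int(rec.sum())),
    }
    for s in SSM_SUBTYPES:
        m = is_ssm & (ann["subtype"] == s)
        out[f"pct_recurrent_ssm[{s}]"] = _pct(int((m & rec).sum()), int(m.sum()))
    for s in SIM_SUBTYPES:
        m = is_sim & ann["is_1bp"] & (ann["subtype"] == s)
        out[f"pct_recurrent_sim[{s}]"] = _pct(int((m & rec).sum()), int(m.sum()))
    return out
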