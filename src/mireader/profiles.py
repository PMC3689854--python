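"""Length-clustered transition-probability profiles over pairing states.

Encoded duplex patterns of the same length are pooled into a cluster, and
for each cluster five subprofiles record how non-match pairing states
co-occur at long range: mismatch with mismatch (X-X), mismatch with
insertion (X-I), mismatch with deletion (X-D), insertion with insertion
(I-I) and deletion with deletion (D-D).  Each subprofile cell (i, j), i < j,
holds a single-order transition probability for the state pair at positions
i and j; the cluster length bounds the maximum transition distance.

A query pattern is scored position by position: every non-match state at j
receives the best transition probability from any earlier non-match state,
and the cluster whose profile maximises the summed score is the pattern's
representative profile.  The per-position scores under that profile are the
feature vector handed to the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .duplex import EncodedPattern

#: the five subprofile families; symmetric families serve both orders
FAMILIES = ("XX", "XI", "XD", "II", "DD")

_FAMILY_OF = {
    ("X", "X"): "XX",
    ("X", "I"): "XI", ("I", "X"): "XI",
    ("X", "D"): "XD", ("D", "X"): "XD",
    ("I", "I"): "II",
    ("D", "D"): "DD",
    # insertion<->deletion transitions have no subprofile and score 0
    ("I", "D"): None, ("D", "I"): None,
}

#: which states at position i condition each family's denominator
_COND_STATES = {
    "XX": ("X",), "XI": ("X", "I"), "XD": ("X", "D"),
    "II": ("I",), "DD": ("D",),
}


@dataclass
class TransitionProfileSet:
    """Five subprofile matrices for one duplex-length cluster."""

    cluster_length: int
    subprofiles: dict[str, np.ndarray]
    training_support: int
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.training_support < 1:
            raise ValueError("training_support must be >= 1")
        for name, mat in self.subprofiles.items():
            if mat.shape != (self.cluster_length, self.cluster_length):
                raise ValueError(f"subprofile {name}: bad shape {mat.shape}")
            if ((mat < 0) | (mat > 1)).any():
                raise ValueError(f"subprofile {name}: probabilities outside [0,1]")

    def cell(self, state_i: str, state_j: str, i: int, j: int) -> float:
        """Transition probability for (state at i -> state at j), i < j;
        0 for pairs with no subprofile (I<->D)."""
        fam = _FAMILY_OF.get((state_i, state_j))
        if fam is None:
            return 0.0
        return float(self.subprofiles[fam][i, j])


@dataclass
class PatternFeatureVector:
    """Positional transition scores of a pattern under its representative
    (highest-scoring) length-cluster profile."""

    values: np.ndarray
    representative_profile: int  # cluster length
    rscore: float
    flagged: bool = False  # routed outside its admissible length band


def _pad_or_truncate(states: str, length: int) -> str:
    """Fit a pattern to a cluster width; M padding contributes no score."""
    if len(states) >= length:
        return states[:length]
    return states + "M" * (length - len(states))


def cluster_patterns(
    patterns: Sequence[EncodedPattern],
    min_support: int = 5,
) -> dict[int, list[str]]:
    """Group patterns by exact length; clusters below ``min_support`` are
    merged into the nearest surviving length cluster (ties toward the
    shorter), padding or truncating their members to fit."""
    by_len: dict[int, list[str]] = {}
    for p in patterns:
        by_len.setdefault(len(p), []).append(p.states)
    keep = sorted(L for L, ps in by_len.items() if len(ps) >= min_support)
    if not keep:
        # nothing reaches support: one merged cluster at the modal length
        if not by_len:
            raise ValueError("empty training set")
        modal = max(by_len, key=lambda L: (len(by_len[L]), -L))
        merged = [
            _pad_or_truncate(s, modal)
            for L in sorted(by_len)
            for s in by_len[L]
        ]
        return {modal: merged}
    clusters: dict[int, list[str]] = {L: list(by_len[L]) for L in keep}
    for L in sorted(set(by_len) - set(keep)):
        target = min(keep, key=lambda k: (abs(k - L), k))
        clusters[target].extend(_pad_or_truncate(s, target) for s in by_len[L])
    return clusters


def build_profiles(
    patterns: Sequence[EncodedPattern],
    pseudocount: float = 0.5,
    min_support: int = 5,
    mode: str = "conditional",
) -> dict[int, TransitionProfileSet]:
    """Build one TransitionProfileSet per length cluster.

    With ``mode="conditional"`` (default) cell (i, j) of family (a, b) is::

        (n[a at i and b at j] + pc) / (n[a at i] + pc * 5)

    counting both orders and conditioning on either state for the symmetric
    families.  ``mode="joint"`` normalises by the cluster size instead.
    Pseudocount smoothing keeps unobserved transitions non-zero so the
    max-scoring step stays robust.
    """
    if mode not in ("conditional", "joint"):
        raise ValueError(f"unknown mode {mode!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    clusters = cluster_patterns(patterns, min_support)
    out: dict[int, TransitionProfileSet] = {}
    for L, members in sorted(clusters.items()):
        arr = np.array([list(s) for s in members])  # (n, L) of state chars
        n = len(members)
        state_at = {st: (arr == st) for st in "XID"}
        subprofiles: dict[str, np.ndarray] = {}
        for fam in FAMILIES:
            a, b = fam[0], fam[1]
            # joint co-occurrence counts over ordered position pairs i < j,
            # both orders of the states for symmetric families
            co = state_at[a].astype(float).T @ state_at[b].astype(float)
            if a != b:
                co = co + state_at[b].astype(float).T @ state_at[a].astype(float)
            if mode == "joint":
                denom = np.full(L, float(n))
            else:
                denom = np.zeros(L)
                for st in _COND_STATES[fam]:
                    denom += state_at[st].sum(axis=0)
            full_denom = denom[:, None] + pseudocount * len(FAMILIES)
            with np.errstate(invalid="ignore", divide="ignore"):
                mat = np.where(full_denom > 0,
                               (co + pseudocount) / full_denom, 0.0)
            mat = np.triu(mat, k=1)  # defined only for i < j
            np.clip(mat, 0.0, 1.0, out=mat)
            subprofiles[fam] = mat
        out[L] = TransitionProfileSet(L, subprofiles, n, pseudocount)
    return out


def score_pattern(
    p: EncodedPattern | str,
    profile: TransitionProfileSet,
) -> tuple[float, np.ndarray]:
    """Score a pattern against one cluster profile.

    Position j with a non-match state scores the maximum transition
    probability from any earlier non-match position i; match positions, and
    non-match positions with no earlier non-match state, score 0.  Returns
    (matrix_score, per-position scores) at the cluster width.
    """
    states = p.states if isinstance(p, EncodedPattern) else p
    bad = set(states) - set("MXID")
    if bad:
        raise ValueError(f"invalid states {sorted(bad)}")
    states = _pad_or_truncate(states, profile.cluster_length)
    scores = np.zeros(profile.cluster_length)
    nonM = [(i, st) for i, st in enumerate(states) if st != "M"]
    for idx, (j, st_j) in enumerate(nonM):
        best = 0.0
        for i, st_i in nonM[:idx]:
            v = profile.cell(st_i, st_j, i, j)
            if v > best:
                best = v
        scores[j] = best
    return float(scores.sum()), scores


def featurize(
    p: EncodedPattern | str,
    profiles: dict[int, TransitionProfileSet],
    length_band: int = 2,
) -> PatternFeatureVector:
    """Score a pattern against every admissible cluster and return the
    positional score vector under the representative (best) profile.

    Clusters within ``length_band`` of the pattern length are admissible
    (patterns are right-padded with inert M states to the cluster width);
    a pattern with no admissible cluster is routed to the nearest-length
    cluster and flagged.  Score ties break toward the better-supported,
    then shorter, cluster.
    """
    if not profiles:
        raise ValueError("no profiles built")
    states = p.states if isinstance(p, EncodedPattern) else p
    Lq = len(states)
    admissible = [L for L in profiles if abs(L - Lq) <= length_band]
    flagged = False
    if not admissible:
        admissible = [min(profiles, key=lambda L: (abs(L - Lq), L))]
        flagged = True
    best = None
    for L in sorted(admissible):
        prof = profiles[L]
        mscore, vec = score_pattern(states, prof)
        key = (-mscore, -prof.training_support, L)
        if best is None or key < best[0]:
            best = (key, L, mscore, vec)
    _, L, mscore, vec = best
    return PatternFeatureVector(vec, L, mscore, flagged)


# ---------------------------------------------------------------------------
# persistence

PROFILE_FORMAT_VERSION = 1


def save_profiles(profiles: dict[int, TransitionProfileSet], path: str | Path) -> None:
    payload = {
        "format_version": PROFILE_FORMAT_VERSION,
        "clusters": {
            str(L): {
                "cluster_length": ps.cluster_length,
                "training_support": ps.training_support,
                "pseudocount": ps.pseudocount,
                "subprofiles": {
                    fam: [[repr(x) for x in row] for row in mat.tolist()]
                    for fam, mat in ps.subprofiles.items()
                },
            }
            for L, ps in sorted(profiles.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def load_profiles(path: str | Path) -> dict[int, TransitionProfileSet]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for L, d in payload["clusters"].items():
        mats = {
            fam: np.array([[float(x) for x in row] for row in mat])
            for fam, mat in d["subprofiles"].items()
        }
        out[int(L)] = TransitionProfileSet(
            d["cluster_length"], mats, d["training_support"], d["pseudocount"]
        )
    return out


def feature_vectors_to_tsv(
    vectors: Sequence[PatternFeatureVector], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("representative_profile\trscore\tflagged\tvalues\n")
        for v in vectors:
            vals = ",".join(f"{x:.6g}" for x in v.values)
            fh.write(f"{v.representative_profile}\t{v.rscore:.6g}\t{int(v.flagged)}\t{vals}\n")
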