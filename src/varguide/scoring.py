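"""Off-target activity scoring: MIT score, CFD score, feature extraction and
Random-Forest activity probabilities.

The MIT score follows the published position-weight formula: over mismatched
positions p (1..20, PAM-distal to PAM-proximal),

    score = prod(1 - W_p) * 1 / (((19 - d) / 19) * 4 + 1) * 1 / m**2

with m the number of mismatches and d the mean pairwise distance between
mismatch positions; a perfect match scores 1 and the distance term is 1 for
a single mismatch.

The CFD score multiplies per-position mismatch penalties and a PAM penalty
looked up from a bundled table.  The bundled table
(``data/cfd_table_synthetic.json``) is a synthetic stand-in that mirrors the
structure of the published cutting-frequency table — positional decay toward
the PAM, transition/transversion/wobble asymmetry, near-zero non-NGG PAM
dinucleotides — with constructed penalty values; a user-supplied table in
the same JSON layout can be passed instead.

The feature schema ("v1") covers three families: mismatch properties
(counts, seed counts, per-position mismatch/transition/transversion
indicators, mean pairwise mismatch distance), sequence context
(position-specific mono- and dinucleotides of the off-target protospacer,
GC content) and the on/off-target PAM relationship.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._dna import BASES, is_transition

PROTO_LEN = 20
SEED_START = 9  # seed region: positions 9..20, the 12 bp next to the PAM

# Published MIT position weights, PAM-distal (position 1) to PAM-proximal
# (position 20).
MIT_WEIGHTS = (
    0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
)


@dataclass(frozen=True)
class MitParams:
    weights: tuple[float, ...] = MIT_WEIGHTS
    distance_norm: float = 19.0
    multiplier: float = 4.0
    offset: float = 1.0

    def __post_init__(self) -> None:
        if len(self.weights) != PROTO_LEN:
            raise ValueError("exactly 20 position weights required")
        if any(not 0.0 <= w <= 1.0 for w in self.weights):
            raise ValueError("weights must lie in [0, 1]")


def _check20(seq: str, what: str) -> str:
    s = seq.upper()
    if len(s) != PROTO_LEN:
        raise ValueError(f"{what} must have length {PROTO_LEN}")
    return s


def mit_score(guide: str, offtarget: str,
              params: MitParams | None = None) -> float:
    """MIT specificity score of one guide/off-target pair, in [0, 1]."""
    params = params or MitParams()
    g = _check20(guide, "guide")
    o = _check20(offtarget, "offtarget")
    positions = [i + 1 for i in range(PROTO_LEN) if g[i] != o[i]]
    m = len(positions)
    if m == 0:
        return 1.0
    prod = 1.0
    for p in positions:
        prod *= 1.0 - params.weights[p - 1]
    if m == 1:
        dist_term = 1.0
    else:
        pairs = list(itertools.combinations(positions, 2))
        d = sum(abs(a - b) for a, b in pairs) / len(pairs)
        dist_term = 1.0 / (((params.distance_norm - d) / params.distance_norm)
                           * params.multiplier + params.offset)
    return prod * dist_term / (m * m)


class CfdLookupError(KeyError):
    """A required penalty is missing from the CFD table."""


@dataclass(frozen=True)
class CfdTable:
    """Mismatch penalties keyed '<pos>:<guide>><offtarget>' and PAM
    penalties keyed by the last two PAM bases; matched positions score 1."""

    mismatch: dict
    pam: dict

    @classmethod
    def bundled(cls) -> "CfdTable":
        raw = json.loads(
            resources.files("varguide.data")
            .joinpath("cfd_table_synthetic.json").read_text())
        return cls(mismatch=raw["mismatch"], pam=raw["pam"])


_BUNDLED_CFD: list[CfdTable] = []


def cfd_score(guide: str, offtarget: str, pam: str,
              table: CfdTable | None = None) -> float:
    """CFD-style score: product of per-mismatch penalties and a PAM penalty."""
    if table is None:
        if not _BUNDLED_CFD:
            _BUNDLED_CFD.append(CfdTable.bundled())
        table = _BUNDLED_CFD[0]
    g = _check20(guide, "guide")
    o = _check20(offtarget, "offtarget")
    if len(pam) != 3:
        raise ValueError("pam must have length 3")
    score = 1.0
    for i in range(PROTO_LEN):
        if g[i] != o[i]:
            key = f"{i + 1}:{g[i]}>{o[i]}"
            try:
                score *= table.mismatch[key]
            except KeyError as exc:
                raise CfdLookupError(f"no CFD penalty for {key}") from exc
    key = pam.upper()[1:]
    try:
        score *= table.pam[key]
    except KeyError as exc:
        raise CfdLookupError(f"no CFD PAM penalty for N{key}") from exc
    return score


# ---------------------------------------------------------------------------
# Feature extraction (schema v1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray
    schema: str = "v1"

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def _schema_v1_names() -> tuple[str, ...]:
    names: list[str] = [
        "mm_total", "mm_seed", "mm_nonseed", "mm_mean_pairwise_dist"]
    names += [f"mm_pos_{p:02d}" for p in range(1, 21)]
    names += [f"transition_pos_{p:02d}" for p in range(1, 21)]
    names += [f"transversion_pos_{p:02d}" for p in range(1, 21)]
    names += [f"nt_{p:02d}_{b}" for p in range(1, 21) for b in BASES]
    names += [f"dint_{p:02d}_{a}{b}" for p in range(1, 20)
              for a in BASES for b in BASES]
    names.append("gc_content")
    names.append("pam_first_base_match")
    names += [f"pam_{p}_{b}" for p in range(1, 4) for b in BASES]
    return tuple(names)


SCHEMA_V1 = _schema_v1_names()
SCHEMAS = {"v1": SCHEMA_V1}


def extract_features(guide: str, offtarget: str,
                     schema: str = "v1") -> FeatureVector:
    """Features of one guide/off-target pair (both 23-mers: 20-mer + PAM)."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown feature schema {schema!r}")
    g23, o23 = guide.upper(), offtarget.upper()
    if len(g23) != 23 or len(o23) != 23:
        raise ValueError("guide and offtarget must be 23-mers (20-mer + PAM)")
    g, o = g23[:PROTO_LEN], o23[:PROTO_LEN]
    gpam, opam = g23[PROTO_LEN:], o23[PROTO_LEN:]
    names = SCHEMAS[schema]
    values = np.zeros(len(names), dtype=np.float64)
    idx = {n: i for i, n in enumerate(names)}

    positions = [p for p in range(1, 21) if g[p - 1] != o[p - 1]]
    values[idx["mm_total"]] = len(positions)
    values[idx["mm_seed"]] = sum(1 for p in positions if p >= SEED_START)
    values[idx["mm_nonseed"]] = sum(1 for p in positions if p < SEED_START)
    if len(positions) >= 2:
        pairs = list(itertools.combinations(positions, 2))
        values[idx["mm_mean_pairwise_dist"]] = \
            sum(abs(a - b) for a, b in pairs) / len(pairs)
    for p in positions:
        values[idx[f"mm_pos_{p:02d}"]] = 1.0
        if is_transition(g[p - 1], o[p - 1]):
            values[idx[f"transition_pos_{p:02d}"]] = 1.0
        else:
            values[idx[f"transversion_pos_{p:02d}"]] = 1.0
    for p in range(1, 21):
        values[idx[f"nt_{p:02d}_{o[p - 1]}"]] = 1.0
    for p in range(1, 20):
        values[idx[f"dint_{p:02d}_{o[p - 1]}{o[p]}"]] = 1.0
    values[idx["gc_content"]] = (o.count("G") + o.count("C")) / PROTO_LEN
    values[idx["pam_first_base_match"]] = float(opam[0] == gpam[0])
    for p in range(1, 4):
        values[idx[f"pam_{p}_{opam[p - 1]}"]] = 1.0
    return FeatureVector(names=names, values=values, schema=schema)


def feature_matrix(on_targets, off_targets, schema: str = "v1"):
    """Feature DataFrame for paired sequences (rows align with inputs)."""
    import pandas as pd

    rows = [extract_features(g, o, schema).values
            for g, o in zip(on_targets, off_targets)]
    return pd.DataFrame(np.vstack(rows) if rows else
                        np.empty((0, len(SCHEMAS[schema]))),
                        columns=list(SCHEMAS[schema]))


def predict_activity(model, features) -> np.ndarray:
    """Forest vote fraction for the active class.

    ``features`` may be a FeatureVector, a DataFrame with named columns, or
    a list of FeatureVectors; columns are aligned to the model's training
    feature names, so feature order never matters.
    """
    import pandas as pd

    if isinstance(features, FeatureVector):
        df = pd.DataFrame([features.as_dict()])
    elif isinstance(features, list):
        df = pd.DataFrame([f.as_dict() for f in features])
    else:
        df = features
    missing = [n for n in model.feature_names if n not in df.columns]
    if missing:
        raise ValueError(
            f"feature schema mismatch: {len(missing)} model features absent "
            f"(first: {missing[0]!r})")
    X = df[list(model.feature_names)]
    active_col = int(np.nonzero(model.forest.classes_ == 1)[0][0])
    return model.forest.predict_proba(X)[:, active_col]


def apply_cutoff(hits: list, threshold: float = 0.5,
                 score_name: str = "rf_probability"):
    """Retain hits whose score is >= threshold; returns (retained, removed)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    retained = [h for h in hits if h.scores.get(score_name, 0.0) >= threshold]
    removed = [h for h in hits if h.scores.get(score_name, 0.0) < threshold]
    return retained, removed
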