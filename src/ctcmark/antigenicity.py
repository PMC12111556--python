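"""Alignment-free antigenicity scoring of protein sequences.

Each sequence is converted to a fixed-length feature vector by the
auto/cross-covariance (ACC) transform of three per-residue physicochemical
z-descriptors (z1 hydrophobicity, z2 steric bulk/size, z3 polarity).  For a
sequence of length n and descriptor pair (j, k) at lag l:

    A_jk(l) = sum_{i=1..n-l} (z_j(i) - mean_j) * (z_k(i+l) - mean_k) / (n - l)

with per-sequence mean-centering of each descriptor column, giving a
3 * 3 * lag vector (components ordered lexicographically by (j, k, l)).
A regularised logistic head trained on labelled ACC vectors turns the
descriptor space into an antigenicity score in [0, 1]; sequences scoring at
or above the threshold (default 0.5) are called antigenic.  The head is
trainable and serialisable, so externally derived discriminant weights can
be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, InputError

#: Three-component z-scales (z1, z2, z3) for the 20 standard residues
#: (principal-property scales derived from physicochemical measurements).
Z_SCALE_VERSION = "z3-classic-1987"
Z_SCALES: dict[str, tuple[float, float, float]] = {
    "A": (0.07, -1.73, 0.09),
    "V": (-2.69, -2.53, -1.29),
    "L": (-4.19, -1.03, -0.98),
    "I": (-4.44, -1.68, -1.03),
    "P": (-1.22, 0.88, 2.23),
    "F": (-4.92, 1.30, 0.45),
    "W": (-4.75, 3.65, 0.85),
    "M": (-2.49, -0.27, -0.41),
    "K": (2.84, 1.41, -3.14),
    "R": (2.88, 2.52, -3.44),
    "H": (2.41, 1.74, 1.11),
    "G": (2.23, -5.36, 0.30),
    "S": (1.96, -1.63, 0.57),
    "T": (0.92, -2.09, -1.40),
    "C": (0.71, -0.97, 4.13),
    "Y": (-1.39, 2.32, 0.01),
    "N": (3.22, 1.45, 0.84),
    "Q": (2.18, 0.53, -1.14),
    "D": (3.64, 1.13, 2.36),
    "E": (3.08, 0.39, -0.07),
}

VALID_RESIDUES = frozenset(Z_SCALES)


@dataclass
class ACCConfig:
    """Auto/cross-covariance transform parameters."""

    lag: int = 8
    center: bool = True
    strip_x: bool = False

    def validate(self) -> None:
        if self.lag < 1:
            raise ConfigurationError("lag must be >= 1")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def validate_sequence(record: SeqRecord, strip_x: bool = False) -> SeqRecord:
    seq = str(record.seq).upper()
    if strip_x:
        seq = seq.replace("X", "")
    for pos, residue in enumerate(seq, start=1):
        if residue not in VALID_RESIDUES:
            raise InputError(
                f"record {record.id!r}: invalid residue {residue!r} at position {pos}"
            )
    return SeqRecord(Seq(seq), id=record.id, description="")


def read_fasta(path: str | Path, strip_x: bool = False) -> list[SeqRecord]:
    """Read protein records from FASTA; ids parsed to the first whitespace.

    Raises :class:`InputError` on an empty file, duplicate ids, or residues
    outside the 20-letter alphabet (unless ``strip_x`` removes X first).
    """
    records = [validate_sequence(r, strip_x=strip_x) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise InputError(f"duplicate FASTA id {r.id!r}")
        seen.add(r.id)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


# ---------------------------------------------------------------------------
# ACC transform
# ---------------------------------------------------------------------------

def _descriptor_matrix(sequence: str) -> np.ndarray:
    """n x 3 matrix of z-descriptors along the sequence."""
    try:
        return np.array([Z_SCALES[res] for res in sequence], dtype=float)
    except KeyError as exc:
        raise InputError(f"invalid residue {exc.args[0]!r}") from exc


def acc_transform(record: SeqRecord | str, cfg: ACCConfig | None = None) -> np.ndarray:
    """ACC feature vector of one sequence: length ``3 * 3 * lag``.

    Components are ordered lexicographically by (descriptor j, descriptor k,
    lag l in 1..lag).  With centering (default), each descriptor column has
    its per-sequence mean subtracted, so homopolymers map to the zero vector.
    """
    cfg = cfg or ACCConfig()
    cfg.validate()
    seq = str(record.seq) if isinstance(record, SeqRecord) else str(record)
    seq = seq.upper()
    n = len(seq)
    if n <= cfg.lag:
        rid = record.id if isinstance(record, SeqRecord) else "<sequence>"
        raise InputError(f"record {rid!r}: length {n} must exceed lag {cfg.lag}")
    z = _descriptor_matrix(seq)
    if cfg.center:
        z = z - z.mean(axis=0, keepdims=True)
    out = np.empty(3 * 3 * cfg.lag)
    idx = 0
    for j in range(3):
        for k in range(3):
            for lag in range(1, cfg.lag + 1):
                out[idx] = np.dot(z[: n - lag, j], z[lag:, k]) / (n - lag)
                idx += 1
    return out


def acc_matrix(records: Sequence[SeqRecord], cfg: ACCConfig | None = None) -> np.ndarray:
    return np.vstack([acc_transform(r, cfg) for r in records])


# ---------------------------------------------------------------------------
# Linear head
# ---------------------------------------------------------------------------

@dataclass
class LinearHead:
    """A trained logistic discriminant over standardised ACC features."""

    weights: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    lag: int
    scale_version: str = Z_SCALE_VERSION

    def decision(self, features: np.ndarray) -> np.ndarray:
        x = (features - self.feature_mean) / self.feature_scale
        return x @ self.weights + self.intercept

    def score(self, features: np.ndarray) -> np.ndarray:
        """Antigenicity probability in [0, 1]."""
        from scipy.special import expit

        return expit(self.decision(features))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "lag": int(self.lag),
            "scale_version": self.scale_version,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearHead":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            weights=np.array(d["weights"], float),
            intercept=float(d["intercept"]),
            feature_mean=np.array(d["feature_mean"], float),
            feature_scale=np.array(d["feature_scale"], float),
            lag=int(d["lag"]),
            scale_version=d["scale_version"],
        )


def train_head(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    lag: int = 8,
    C: float = 1.0,
) -> LinearHead:
    """Fit a regularised logistic discriminant on labelled ACC vectors.

    Features are standardised (zero mean, unit variance per component)
    before the fit; the head stores the standardisation so scoring is
    self-contained.  Deterministic: L-BFGS on a convex objective.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(labels, dtype=int)
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise InputError("features must be a 2-D array aligned with labels")
    if len(np.unique(y)) < 2:
        raise InputError("training labels must contain both classes")
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    clf = LogisticRegression(C=C, max_iter=2000, solver="lbfgs")
    clf.fit(xs, y)
    return LinearHead(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_mean=mean,
        feature_scale=scale,
        lag=lag,
    )


def score_sequences(
    records: Sequence[SeqRecord],
    head: LinearHead,
    threshold: float = 0.5,
    cfg: ACCConfig | None = None,
) -> pd.DataFrame:
    """Score records with a trained head.

    Returns a DataFrame with columns ``id``, ``score`` and ``antigenic``
    (score >= threshold).
    """
    cfg = cfg or ACCConfig(lag=head.lag)
    if cfg.lag != head.lag:
        raise ConfigurationError(f"ACC lag {cfg.lag} differs from head lag {head.lag}")
    if not records:
        return pd.DataFrame(columns=["id", "score", "antigenic"])
    scores = head.score(acc_matrix(records, cfg))
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "score": scores,
            "antigenic": scores >= threshold,
        }
    )
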