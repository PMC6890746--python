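"""Transparent coding-potential screen for transcript sequences.

Differentially expressed lncRNA candidates are screened to confirm they have
no peptide-coding capability.  Rather than reproducing a trained SVM, the
screen combines three classical, fully deterministic sequence features --
longest forward-frame ORF length, ORF coverage of the transcript, and the
TESTCODE (Fickett) statistic computed from published position/composition
lookup tables -- through a fixed logistic model whose coefficients ship as a
versioned data file.  A transcript is labelled ``noncoding`` when its coding
probability falls strictly below the screening threshold (0.37 by default).

Transcript sequences are assumed stranded (sense orientation); only the
three forward frames are scanned.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import AnalysisError, FormatError

logger = logging.getLogger(__name__)

NONCODING_THRESHOLD = 0.37
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class CodingFeatures:
    """Per-transcript coding-potential features and label."""

    transcript_id: str
    length_nt: int
    longest_orf_nt: int
    orf_coverage: float
    fickett_score: float
    coding_probability: float
    label: str  # "coding" | "noncoding"


@lru_cache(maxsize=1)
def _fickett_tables() -> dict:
    ref = resources.files("ccmlnc").joinpath("data/fickett_tables.json")
    return json.loads(ref.read_text())


@lru_cache(maxsize=1)
def _coding_model() -> dict:
    ref = resources.files("ccmlnc").joinpath("data/coding_model.json")
    return json.loads(ref.read_text())


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise AnalysisError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise FormatError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return seq


def longest_orf(sequence: str) -> tuple[int, int, int]:
    """Longest ATG-to-stop open reading frame in the three forward frames.

    Returns ``(start, end, length_nt)`` in 0-based half-open coordinates;
    the length includes the stop codon.  ORFs containing an N anywhere are
    skipped.  Nested starts are absorbed: an ORF runs from its first ATG, so
    the outermost reading wins.  ``(0, 0, 0)`` when no complete ORF exists.
    """
    seq = _validate_sequence(sequence)
    best = (0, 0, 0)
    for frame in range(3):
        start: int | None = None
        has_n = False
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
                    has_n = False
            else:
                if "N" in codon:
                    has_n = True
                elif codon in STOP_CODONS:
                    length = pos + 3 - start
                    if not has_n and length > best[2]:
                        best = (start, pos + 3, length)
                    start = None
    return best


def fickett_score(sequence: str) -> float:
    """TESTCODE statistic from positional asymmetry and base composition.

    For each base the positional parameter is ``max(n1, n2, n3) /
    (min(n1, n2, n3) + 1)`` over the three codon-phase position classes, and
    the compositional parameter is the base's overall frequency; both are
    converted to probabilities through the published lookup tables and
    combined as a weighted sum.  N positions are ignored.  Sequences shorter
    than 200 nt are scored with a warning (the statistic is unreliable
    there).
    """
    seq = _validate_sequence(sequence)
    if len(seq) < 200:
        logger.warning("fickett_score: sequence shorter than 200 nt (%d)", len(seq))
    tables = _fickett_tables()
    score = 0.0
    total = sum(1 for ch in seq if ch != "N")
    for base in "ACGT":
        phase_counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                phase_counts[i % 3] += 1
        position_value = max(phase_counts) / (min(phase_counts) + 1)
        content_value = sum(phase_counts) / total if total else 0.0
        score += _lookup(
            position_value, tables["position_thresholds"], tables["position_prob"][base]
        ) * tables["position_weight"][base]
        score += _lookup(
            content_value, tables["content_thresholds"], tables["content_prob"][base]
        ) * tables["content_weight"][base]
    return score


def _lookup(value: float, thresholds: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(thresholds, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_bounds() -> tuple[float, float]:
    """Attainable [min, max] of the TESTCODE score given the lookup tables."""
    tables = _fickett_tables()
    lo = hi = 0.0
    for base in "ACGT":
        for kind in ("position", "content"):
            probs = tables[f"{kind}_prob"][base]
            w = tables[f"{kind}_weight"][base]
            lo += min(probs) * w
            hi += max(probs) * w
    return lo, hi


def coding_probability(
    longest_orf_nt: int, orf_coverage: float, fickett: float
) -> float:
    """Fixed logistic combination of the three features (coefficients from
    the versioned model file)."""
    model = _coding_model()
    coef = model["coefficients"]
    z = (
        model["intercept"]
        + coef["longest_orf_nt"] * longest_orf_nt
        + coef["orf_coverage"] * orf_coverage
        + coef["fickett_score"] * fickett
    )
    return 1.0 / (1.0 + math.exp(-z))


def compute_features(
    transcript_id: str, sequence: str, threshold: float = NONCODING_THRESHOLD
) -> CodingFeatures:
    """All coding-potential features plus the threshold label for one transcript."""
    seq = _validate_sequence(sequence)
    _, _, orf_nt = longest_orf(seq)
    coverage = orf_nt / len(seq)
    fick = fickett_score(seq)
    prob = coding_probability(orf_nt, coverage, fick)
    return CodingFeatures(
        transcript_id=transcript_id,
        length_nt=len(seq),
        longest_orf_nt=orf_nt,
        orf_coverage=coverage,
        fickett_score=fick,
        coding_probability=prob,
        label=classify_coding(prob, threshold),
    )


def classify_coding(
    coding_prob: float, threshold: float = NONCODING_THRESHOLD
) -> str:
    """``noncoding`` iff the coding probability is strictly below the threshold."""
    return "noncoding" if coding_prob < threshold else "coding"


def screen_fasta(
    path: str | Path,
    transcript_ids: Iterable[str] | None = None,
    threshold: float = NONCODING_THRESHOLD,
) -> pd.DataFrame:
    """Screen transcripts in a FASTA file; returns a feature/label table.

    With ``transcript_ids`` only those records are screened (ids absent from
    the file are reported with NaN features and label ``missing``).
    """
    wanted = set(transcript_ids) if transcript_ids is not None else None
    rows = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if wanted is not None and record.id not in wanted:
            continue
        feats = compute_features(record.id, str(record.seq), threshold)
        seen.add(record.id)
        rows.append(feats.__dict__)
    if wanted is not None:
        for missing in sorted(wanted - seen):
            rows.append(
                dict(
                    transcript_id=missing,
                    length_nt=0,
                    longest_orf_nt=0,
                    orf_coverage=float("nan"),
                    fickett_score=float("nan"),
                    coding_probability=float("nan"),
                    label="missing",
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "length_nt",
            "longest_orf_nt",
            "orf_coverage",
            "fickett_score",
            "coding_probability",
            "label",
        ],
    )
    return df.set_index("transcript_id")
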