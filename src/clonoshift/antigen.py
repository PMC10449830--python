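"""Antigen-signature partitioning of TCR repertoires.

An antigen signature is a set of CDR3-beta amino-acid sequences known to
confer reactivity to one epitope (the motivating case is AH1, an H2-Ld
restricted epitope of an endogenous retroviral gp70 protein expressed by
4T1 mammary carcinoma cells).  Matching is exact CDR3B equality; inferring
specificity from the beta chain alone is an approximation and fuzzy/motif
matching is deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .diversity import clonality
from .errors import DataError
from .repertoire import Repertoire

logger = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TCRSignature:
    """Named set of CDR3B amino-acid sequences defining antigen reactivity."""

    name: str
    cdr3b_sequences: frozenset

    def __post_init__(self) -> None:
        if not self.cdr3b_sequences:
            raise DataError(f"signature {self.name!r} is empty")
        bad = [
            s
            for s in self.cdr3b_sequences
            if not s or not set(s) <= _AA
        ]
        if bad:
            raise DataError(
                f"signature {self.name!r}: non-amino-acid sequences {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.cdr3b_sequences)


def read_signature(path: str | Path, name: str | None = None) -> TCRSignature:
    """Read a signature file: one CDR3B per line, or two-column TSV
    (sequence, label)."""
    path = Path(path)
    seqs = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seqs.append(line.split("\t")[0].upper())
    return TCRSignature(name or path.stem, frozenset(seqs))


@dataclass
class SignaturePartition:
    """A repertoire split into signature-matched and unmatched clones.

    ``signature_frequency`` is the matched mass on the *original* frequency
    scale; both sub-repertoires are renormalized so downstream clonality
    operates on probability vectors.  Either side may be None when empty.
    """

    matched: Repertoire | None
    unmatched: Repertoire | None
    signature_frequency: float


def match_signature(rep: Repertoire, sig: TCRSignature) -> SignaturePartition:
    """Partition a TRB repertoire by exact CDR3B membership in ``sig``."""
    if rep.chain != "TRB":
        raise DataError(
            f"sample {rep.sample_id!r}: signature matching needs a TRB "
            f"repertoire (got {rep.chain})"
        )
    in_sig = rep.clones["cdr3_aa"].isin(sig.cdr3b_sequences)
    sig_freq = float(rep.clones.loc[in_sig, "frequency"].sum())

    def _sub(mask) -> Repertoire | None:
        sub = rep.clones[mask]
        if len(sub) == 0:
            return None
        return replace(rep, clones=sub.reset_index(drop=True)).normalized()

    return SignaturePartition(
        matched=_sub(in_sig),
        unmatched=_sub(~in_sig),
        signature_frequency=sig_freq,
    )


def partitioned_clonality(
    part: SignaturePartition,
) -> tuple[float | None, float | None]:
    """Clonality of each renormalized sub-repertoire (None when empty)."""
    out = []
    for side, rep in (("matched", part.matched), ("unmatched", part.unmatched)):
        if rep is None:
            logger.warning("empty %s partition: clonality undefined", side)
            out.append(None)
        else:
            out.append(clonality(rep))
    return tuple(out)


def jaccard_overlap(
    rep_a: Repertoire,
    rep_b: Repertoire,
    sig: TCRSignature,
    include_vj: bool = False,
) -> float:
    """Jaccard index of the signature-matched clone sets of two samples.

    Used to quantify sharing of the antigen-reactive repertoire between
    paired compartments (tumor vs draining lymph node).  Set-based, hence
    invariant to clone frequency.  The clone key is the CDR3B sequence (the
    level at which the signature is defined); ``include_vj`` switches to the
    (CDR3B, V, J) key.  Both-empty sets give 0 with a warning.
    """

    def _sig_keys(rep: Repertoire) -> set:
        m = rep.clones[rep.clones["cdr3_aa"].isin(sig.cdr3b_sequences)]
        if include_vj:
            return set(zip(m["cdr3_aa"], m["v_gene"], m["j_gene"]))
        return set(m["cdr3_aa"])

    a, b = _sig_keys(rep_a), _sig_keys(rep_b)
    union = a | b
    if not union:
        logger.warning(
            "samples %s/%s: no signature-matched clones in either sample; "
            "Jaccard set to 0",
            rep_a.sample_id,
            rep_b.sample_id,
        )
        return 0.0
    return len(a & b) / len(union)
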