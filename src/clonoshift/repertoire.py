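"""Clonotype tables: data model, I/O dialects, filtering, and top-N subsetting.

A *clonotype* is a unique TCR rearrangement keyed by (CDR3 amino-acid
sequence, V gene, J gene, chain) with an abundance in one sample.  A
*repertoire* is the clone list of a single sample.  Everything downstream
(clonality, divergence, antigen partitioning) consumes the ``Repertoire``
produced here.

Clone tables arrive as TSV in vendor-specific layouts; the column maps are
data, not code (see ``DIALECTS``), so a new dialect is one dictionary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

#: canonical per-clone columns, in output order
CLONE_COLUMNS = [
    "cdr3_aa",
    "cdr3_nt",
    "v_gene",
    "j_gene",
    "count",
    "frequency",
    "productive",
]

#: identity key for a clone within a repertoire (chain is repertoire-level)
CLONE_KEY = ["cdr3_aa", "v_gene", "j_gene"]

# Each dialect maps canonical field -> input column name.  ``freq_scale``
# divides the frequency column (immunoSEQ reports percent);
# ``productive_true`` is the token meaning a productive rearrangement
# (None -> all rows assumed productive, as for vendor tables that ship
# pre-filtered).
DIALECTS: dict[str, dict] = {
    "irepertoire": {
        "columns": {
            "cdr3_aa": "CDR3_AA",
            "cdr3_nt": "CDR3_NT",
            "v_gene": "V",
            "j_gene": "J",
            "count": "Reads",
            "frequency": "Frequency",
        },
        "freq_scale": 1.0,
        "productive_column": None,
        "productive_true": None,
    },
    "immunoseq": {
        "columns": {
            "cdr3_aa": "aminoAcid",
            "cdr3_nt": "nucleotide",
            "v_gene": "vGeneName",
            "j_gene": "jGeneName",
            "count": "count (templates/reads)",
            "frequency": "frequencyCount (%)",
        },
        "freq_scale": 100.0,
        "productive_column": "sequenceStatus",
        "productive_true": "In",
    },
    "airr-min": {
        "columns": {
            "cdr3_aa": "junction_aa",
            "cdr3_nt": "junction",
            "v_gene": "v_call",
            "j_gene": "j_call",
            "count": "duplicate_count",
            "frequency": "duplicate_frequency",
        },
        "freq_scale": 1.0,
        "productive_column": "productive",
        "productive_true": "T",
    },
    "canonical": {
        "columns": {
            "cdr3_aa": "cdr3_aa",
            "cdr3_nt": "cdr3_nt",
            "v_gene": "v_gene",
            "j_gene": "j_gene",
            "count": "count",
            "frequency": "frequency",
        },
        "freq_scale": 1.0,
        "productive_column": "productive",
        "productive_true": "True",
    },
}

#: columns a table must provide (count or frequency may substitute for each other)
_MANDATORY_FIELDS = ["cdr3_aa", "v_gene", "j_gene"]


@dataclass
class Repertoire:
    """The clone list of one sample.

    Parameters
    ----------
    sample_id
        Sample label (mouse/patient + tissue + timepoint as convenient).
    chain
        ``"TRA"`` or ``"TRB"``.
    clones
        DataFrame with columns :data:`CLONE_COLUMNS`; one row per unique
        clone key, frequencies summing to 1 after :meth:`normalized`.
    tissue
        ``"tumor"``, ``"dLN"`` or ``"other"``.
    timepoint
        ``"pre"``, ``"post"`` or ``"NA"``.
    """

    sample_id: str
    chain: str
    clones: pd.DataFrame = field(repr=False)
    tissue: str = "other"
    timepoint: str = "NA"

    def __post_init__(self) -> None:
        if self.chain not in ("TRA", "TRB"):
            raise DataError(f"unknown chain {self.chain!r} (expected TRA or TRB)")
        missing = [c for c in CLONE_COLUMNS if c not in self.clones.columns]
        if missing:
            raise FormatError(f"clone table missing columns {missing}")
        if len(self.clones) == 0:
            raise DataError(f"sample {self.sample_id!r}: empty repertoire")

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def frequencies(self) -> np.ndarray:
        return self.clones["frequency"].to_numpy(dtype=float)

    def normalized(self) -> "Repertoire":
        """Return a copy with frequencies rescaled to sum to 1."""
        total = float(self.clones["frequency"].sum())
        if total <= 0:
            raise DataError(f"sample {self.sample_id!r}: nonpositive total frequency")
        clones = self.clones.copy()
        clones["frequency"] = clones["frequency"] / total
        return replace(self, clones=clones)

    def check_normalized(self, tol: float = 1e-6) -> None:
        total = float(self.clones["frequency"].sum())
        if abs(total - 1.0) > tol:
            raise DataError(
                f"sample {self.sample_id!r}: frequencies sum to {total:.6g}, not 1"
            )


def _aggregate_clone_keys(clones: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (cdr3_aa, v_gene, j_gene) rows by summing abundance."""
    if not clones.duplicated(subset=CLONE_KEY).any():
        return clones
    agg = clones.groupby(CLONE_KEY, as_index=False, sort=False).agg(
        cdr3_nt=("cdr3_nt", "first"),
        count=("count", "sum"),
        frequency=("frequency", "sum"),
        productive=("productive", "all"),
    )
    logger.info("aggregated %d duplicate clone keys", len(clones) - len(agg))
    return agg[CLONE_COLUMNS]


def read_clonotype_table(
    path: str | Path,
    dialect: str,
    sample_id: str | None = None,
    chain: str = "TRB",
    tissue: str = "other",
    timepoint: str = "NA",
) -> Repertoire:
    """Read a clonotype TSV into a :class:`Repertoire`.

    Frequencies are taken verbatim when the table carries them (rescaled from
    percent for immunoSEQ), otherwise computed from counts.  Duplicate clone
    keys are aggregated by summing abundance.

    Raises
    ------
    ConfigError
        Unknown dialect name.
    FormatError
        Mandatory columns absent (the message names them).
    DataError
        Empty table.
    """
    if dialect not in DIALECTS:
        raise ConfigError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        )
    layout = DIALECTS[dialect]
    colmap = layout["columns"]
    path = Path(path)
    # keep_default_na=False so empty optional fields (cdr3_nt) stay ""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [
        colmap[f] for f in _MANDATORY_FIELDS if colmap[f] not in table.columns
    ]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory columns {missing}")
    has_count = colmap["count"] in table.columns
    has_freq = colmap["frequency"] in table.columns
    if not (has_count or has_freq):
        raise FormatError(
            f"{path.name}: need a count ({colmap['count']!r}) or frequency "
            f"({colmap['frequency']!r}) column"
        )
    if len(table) == 0:
        raise DataError(f"{path.name}: empty clonotype table")

    clones = pd.DataFrame(
        {
            "cdr3_aa": table[colmap["cdr3_aa"]].astype(str),
            "cdr3_nt": (
                table[colmap["cdr3_nt"]].astype(str)
                if colmap["cdr3_nt"] in table.columns
                else ""
            ),
            "v_gene": table[colmap["v_gene"]].astype(str),
            "j_gene": table[colmap["j_gene"]].astype(str),
        }
    )
    clones["count"] = (
        pd.to_numeric(table[colmap["count"]], errors="coerce")
        if has_count
        else np.nan
    )
    if has_freq:
        clones["frequency"] = (
            pd.to_numeric(table[colmap["frequency"]]) / layout["freq_scale"]
        )
    else:
        total = clones["count"].sum()
        if total <= 0:
            raise DataError(f"{path.name}: all counts are zero")
        clones["frequency"] = clones["count"] / total

    prod_col = layout["productive_column"]
    if prod_col is not None and prod_col in table.columns:
        clones["productive"] = (
            table[prod_col].astype(str) == str(layout["productive_true"])
        )
    else:
        clones["productive"] = True

    clones = _aggregate_clone_keys(clones[CLONE_COLUMNS])

    if sample_id is None:
        sample_id = path.stem
    if dialect == "canonical":
        if "sample_id" in table.columns:
            sample_id = str(table["sample_id"].iloc[0])
        if "chain" in table.columns:
            chain = str(table["chain"].iloc[0])
    return Repertoire(
        sample_id=sample_id,
        chain=chain,
        clones=clones.reset_index(drop=True),
        tissue=tissue,
        timepoint=timepoint,
    )


def write_clonotype_table(
    rep: Repertoire, path: str | Path, dialect: str = "canonical"
) -> None:
    """Write a repertoire as a TSV in the given dialect's column layout."""
    if dialect not in DIALECTS:
        raise ConfigError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        )
    layout = DIALECTS[dialect]
    colmap = layout["columns"]
    out = pd.DataFrame()
    if dialect == "canonical":
        out["sample_id"] = [rep.sample_id] * len(rep.clones)
        out["chain"] = rep.chain
    for fld in ["cdr3_aa", "cdr3_nt", "v_gene", "j_gene", "count"]:
        out[colmap[fld]] = rep.clones[fld].values
    out[colmap["frequency"]] = rep.clones["frequency"].values * layout["freq_scale"]
    prod_col = layout["productive_column"]
    if prod_col is not None:
        if dialect == "immunoseq":
            out[prod_col] = np.where(rep.clones["productive"], "In", "Out")
        elif dialect == "airr-min":
            out[prod_col] = np.where(rep.clones["productive"], "T", "F")
        else:
            out[prod_col] = rep.clones["productive"].values
    out.to_csv(path, sep="\t", index=False)


def filter_repertoire(
    rep: Repertoire,
    min_frequency: float = 2e-5,
    productive_only: bool = True,
    renormalize: bool = True,
) -> Repertoire:
    """Remove non-productive and rare clones.

    Clones with frequency <= ``min_frequency`` (the retained set is frequency
    strictly above threshold) are dropped, as are non-productive
    rearrangements when ``productive_only``.  The default threshold 2e-5 is
    the depth floor below which single-read artifacts dominate deep bulk
    TCR sequencing.

    Raises :class:`DataError` (naming the sample) if nothing survives.
    """
    keep = rep.clones["frequency"] > min_frequency
    if productive_only:
        keep &= rep.clones["productive"].astype(bool)
    kept = rep.clones[keep]
    if len(kept) == 0:
        raise DataError(
            f"sample {rep.sample_id!r}: no clones pass the filter "
            f"(min_frequency={min_frequency}, productive_only={productive_only})"
        )
    out = replace(rep, clones=kept.reset_index(drop=True))
    if renormalize:
        out = out.normalized()
    return out


def _sorted_clones(clones: pd.DataFrame) -> pd.DataFrame:
    """Deterministic abundance order: frequency desc, then count desc, then
    lexicographic (cdr3_aa, v_gene, j_gene) to break exact ties."""
    count_key = clones["count"].fillna(-1.0)
    order = (
        clones.assign(_count_key=count_key)
        .sort_values(
            by=["frequency", "_count_key", "cdr3_aa", "v_gene", "j_gene"],
            ascending=[False, False, True, True, True],
            kind="mergesort",
        )
        .drop(columns="_count_key")
    )
    return order


def top_n_subset(rep: Repertoire, n: int, renormalize: bool = True) -> Repertoire:
    """Keep the ``n`` most frequent clones (all of them if fewer, with a
    logged warning), deterministically tie-broken, optionally renormalized.

    Used both for the top-500 normalized clonality sensitivity check and the
    top-700 rank-divergence construction.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rep.n_clones < n:
        logger.warning(
            "sample %s: requested top %d of %d clones; keeping all",
            rep.sample_id,
            n,
            rep.n_clones,
        )
    kept = _sorted_clones(rep.clones).head(n).reset_index(drop=True)
    out = replace(rep, clones=kept)
    if renormalize:
        out = out.normalized()
    return out
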