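"""GWAS summary-statistic data model, I/O and exposure–outcome harmonization.

A trait's associations are held as a :class:`SummaryStatSet` (one row per
SNP).  Two traits are combined into a :class:`HarmonizedTable`, in which each
retained row expresses the exposure and outcome effects relative to the same
effect allele.  LD information for clumping lives in :class:`LDReference`.

Positions are 1-based.  No strand column is modelled: strand is resolved only
through allele complementation, which is why palindromic (A/T, C/G) variants
need special handling during harmonization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SummaryStatParseError

__all__ = [
    "SUMMARY_COLUMNS",
    "SummaryStatSet",
    "HarmonizedTable",
    "LDReference",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_reference",
    "harmonize",
]

#: canonical column order of the internal schema
SUMMARY_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

TRAIT_ROLES = ("exposure", "outcome", "covariate")
TAXON_LEVELS = ("phylum", "class", "order", "family", "genus", "none")


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    df = df[SUMMARY_COLUMNS].copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            raise SummaryStatParseError(
                f"invalid allele in column {col!r}: {sorted(df.loc[bad, col].unique())}"
            )
    if (df["effect_allele"] == df["other_allele"]).any():
        offender = df.loc[df["effect_allele"] == df["other_allele"], "snp_id"].iloc[0]
        raise SummaryStatParseError(f"effect and other allele identical for {offender}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise SummaryStatParseError(f"duplicate snp_id {dup!r}")
    if (df["se"] <= 0).any():
        raise SummaryStatParseError("se must be > 0 for every record")
    eaf = df["eaf"]
    if ((eaf < 0) | (eaf > 1)).any():
        raise SummaryStatParseError("eaf must lie in [0, 1] (NaN allowed)")
    if (df["pos"] < 1).any():
        raise SummaryStatParseError("pos must be >= 1")
    return df


@dataclass
class SummaryStatSet:
    """Per-SNP GWAS associations for one trait.

    Parameters
    ----------
    trait_name
        Human-readable trait label, e.g. ``"nicotine_dependence"`` or a
        bacterial taxon name.
    records
        DataFrame with columns :data:`SUMMARY_COLUMNS`; one row per SNP,
        ``snp_id`` unique.
    trait_role
        ``exposure`` / ``outcome`` / ``covariate``.
    taxon_level
        One of phylum/class/order/family/genus, or ``none`` for non-taxon
        traits.
    """

    trait_name: str
    records: pd.DataFrame
    trait_role: str = "exposure"
    taxon_level: str = "none"

    def __post_init__(self):
        if self.trait_role not in TRAIT_ROLES:
            raise ConfigurationError(f"trait_role must be one of {TRAIT_ROLES}")
        if self.taxon_level not in TAXON_LEVELS:
            raise ConfigurationError(f"taxon_level must be one of {TAXON_LEVELS}")
        self.records = _validate_records(
            self.records.reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.records["snp_id"])

    def replace_records(self, records: pd.DataFrame) -> "SummaryStatSet":
        """New set with the same trait metadata but different records."""
        return SummaryStatSet(
            trait_name=self.trait_name,
            records=records,
            trait_role=self.trait_role,
            taxon_level=self.taxon_level,
        )


@dataclass
class HarmonizedTable:
    """Exposure and outcome effects aligned to a common effect allele.

    ``table`` holds the retained rows (columns ``snp_id, beta_exp, se_exp,
    eaf_exp, n_exp, beta_out, se_out, eaf_out, n_out, palindromic``);
    ``dropped`` records the SNPs lost to harmonization together with a
    machine-readable reason code.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    COLUMNS = [
        "snp_id",
        "beta_exp",
        "se_exp",
        "eaf_exp",
        "n_exp",
        "beta_out",
        "se_out",
        "eaf_out",
        "n_out",
        "palindromic",
    ]

    def __post_init__(self):
        if list(self.table.columns) != self.COLUMNS:
            missing = [c for c in self.COLUMNS if c not in self.table.columns]
            if missing:
                raise ConfigurationError(f"harmonized table missing columns {missing}")
            self.table = self.table[self.COLUMNS]
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        t = self.table
        return (
            t["beta_exp"].to_numpy(float),
            t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float),
            t["se_out"].to_numpy(float),
        )

    def subset(self, keep: "np.ndarray | list") -> "HarmonizedTable":
        """Rows selected by boolean mask or list of snp_ids."""
        if isinstance(keep, (list, tuple, set, pd.Index)):
            mask = self.table["snp_id"].isin(list(keep)).to_numpy()
        else:
            mask = np.asarray(keep, dtype=bool)
        return HarmonizedTable(table=self.table.loc[mask].reset_index(drop=True))

    def drop_snps(self, snp_ids) -> "HarmonizedTable":
        mask = ~self.table["snp_id"].isin(list(snp_ids)).to_numpy()
        return HarmonizedTable(table=self.table.loc[mask].reset_index(drop=True))

    @classmethod
    def from_arrays(
        cls,
        snp_id,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        eaf_exp=None,
        n_exp=np.nan,
        eaf_out=None,
        n_out=np.nan,
    ) -> "HarmonizedTable":
        """Build a table directly from effect arrays (synthetic workflows)."""
        k = len(snp_id)
        table = pd.DataFrame(
            {
                "snp_id": list(snp_id),
                "beta_exp": np.asarray(beta_exp, float),
                "se_exp": np.asarray(se_exp, float),
                "eaf_exp": np.full(k, np.nan) if eaf_exp is None else np.asarray(eaf_exp, float),
                "n_exp": np.broadcast_to(np.asarray(n_exp, float), (k,)).copy(),
                "beta_out": np.asarray(beta_out, float),
                "se_out": np.asarray(se_out, float),
                "eaf_out": np.full(k, np.nan) if eaf_out is None else np.asarray(eaf_out, float),
                "n_out": np.broadcast_to(np.asarray(n_out, float), (k,)).copy(),
                "palindromic": np.zeros(k, bool),
            }
        )
        return cls(table=table)


class LDReference:
    """Pairwise r² records plus a per-SNP position map.

    Pairs are stored unordered: ``r2(a, b) == r2(b, a)``.  A SNP's r² with
    itself is 1 and pairs absent from the reference are treated as r² = 0 by
    consumers (greedy clumping).
    """

    def __init__(self, pairs: pd.DataFrame | None, positions: pd.DataFrame):
        # positions: snp_id, chrom, pos
        pos = positions[["snp_id", "chrom", "pos"]].drop_duplicates("snp_id")
        self._positions = {
            s: (str(c), int(p))
            for s, c, p in zip(pos["snp_id"], pos["chrom"], pos["pos"])
        }
        self._r2: dict[tuple[str, str], float] = {}
        if pairs is not None and len(pairs):
            for a, b, r2 in zip(pairs["snp_id_a"], pairs["snp_id_b"], pairs["r2"]):
                r2 = float(r2)
                if not 0.0 <= r2 <= 1.0:
                    raise ConfigurationError(f"r2 out of [0,1] for pair ({a}, {b})")
                self._r2[(a, b) if a <= b else (b, a)] = r2

    def has_position(self, snp_id: str) -> bool:
        return snp_id in self._positions

    def position(self, snp_id: str) -> tuple[str, int]:
        return self._positions[snp_id]

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get((a, b) if a <= b else (b, a), 0.0)

    def pairs_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["snp_id_a", "snp_id_b", "r2"])

    def positions_frame(self) -> pd.DataFrame:
        rows = [(s, c, p) for s, (c, p) in sorted(self._positions.items())]
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_summary_stats(
    path,
    dialect: dict[str, str] | None = None,
    trait_name: str | None = None,
    trait_role: str = "exposure",
    taxon_level: str = "none",
    sep: str = "\t",
) -> SummaryStatSet:
    """Read a delimited summary-statistics file into a :class:`SummaryStatSet`.

    ``dialect`` maps internal column names to the file's header names, so
    consortium-specific headers (``SNP``, ``effect_allele.exposure``, ...)
    can be read without rewriting the file.  Gzip input is transparent.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, compression="infer")
    mapping = {internal: internal for internal in SUMMARY_COLUMNS}
    if dialect:
        mapping.update(dialect)
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped column(s) {missing} not found in header {list(raw.columns)}"
        )
    df = pd.DataFrame({internal: raw[src] for internal, src in mapping.items()})

    for col in ("eaf", "beta", "se", "pvalue"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any() and col in ("beta", "se"):
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise SummaryStatParseError(
                f"{path}: non-numeric {col} {df.loc[bad.idxmax(), col]!r} on line {line}"
            )
        df[col] = parsed
    for col in ("pos", "n"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            line = int(parsed.isna().idxmax()) + 2
            raise SummaryStatParseError(f"{path}: non-numeric {col} on line {line}")
        df[col] = parsed.astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)

    return SummaryStatSet(
        trait_name=trait_name or str(path),
        records=df,
        trait_role=trait_role,
        taxon_level=taxon_level,
    )


def write_summary_stats(sset: SummaryStatSet, path, allow_empty: bool = False) -> None:
    """Write a set as TSV, deterministically sorted by (chrom, pos, snp_id)."""
    if len(sset) == 0 and not allow_empty:
        raise ConfigurationError("refusing to write an empty SummaryStatSet")
    out = sset.records.sort_values(
        ["chrom", "pos", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def read_ld_reference(pairs_path, positions: pd.DataFrame | SummaryStatSet) -> LDReference:
    """Read a pairwise r² TSV (snp_id_a, snp_id_b, r2); positions supplied
    separately, either as a frame or taken from a summary-stat set."""
    pairs = pd.read_csv(pairs_path, sep="\t", compression="infer")
    if isinstance(positions, SummaryStatSet):
        positions = positions.records[["snp_id", "chrom", "pos"]]
    return LDReference(pairs, positions)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_policy: str = "drop_ambiguous",
    ambiguous_maf: float = 0.42,
) -> HarmonizedTable:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    For each SNP shared between the two studies the outcome alleles are
    matched to the exposure alleles directly, after swapping (flip the sign
    of ``beta_out`` and replace ``eaf_out`` by ``1 - eaf_out``), or after a
    strand flip (A<->T, C<->G); anything else is dropped with reason
    ``allele_mismatch``.  Palindromic SNPs cannot be strand-resolved from
    alleles alone and are handled per ``palindrome_policy``:

    ``drop_ambiguous`` (default)
        Drop when the minor-allele frequency exceeds ``ambiguous_maf`` in
        either study, or when either frequency is missing; otherwise orient
        so the allele frequencies agree (< 0.5 on the same side).
    ``drop_all``
        Drop every palindromic SNP.
    ``keep``
        Trust the reported strands and align by allele letters only.
    """
    if palindrome_policy not in ("drop_ambiguous", "drop_all", "keep"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")

    exp = exposure.records.set_index("snp_id")
    out = outcome.records.set_index("snp_id")

    retained_rows = []
    dropped_rows = []
    for snp in exp.index:
        e = exp.loc[snp]
        if snp not in out.index:
            dropped_rows.append((snp, "not_in_outcome"))
            continue
        o = out.loc[snp]
        ea, oa = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        palindromic = _is_palindromic(ea, oa)

        flip = None  # None -> mismatch
        if (ea_o, oa_o) == (ea, oa):
            flip = False
        elif (ea_o, oa_o) == (oa, ea):
            flip = True
        elif not palindromic:
            # try strand-flipping the outcome's alleles
            c_ea, c_oa = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
            if (c_ea, c_oa) == (ea, oa):
                flip = False
            elif (c_ea, c_oa) == (oa, ea):
                flip = True
        if flip is None:
            dropped_rows.append((snp, "allele_mismatch"))
            continue

        beta_out = -float(o["beta"]) if flip else float(o["beta"])
        eaf_out = float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
        if flip and not np.isnan(eaf_out):
            eaf_out = 1.0 - eaf_out
        eaf_exp = float(e["eaf"]) if pd.notna(e["eaf"]) else np.nan

        if palindromic:
            if palindrome_policy == "drop_all":
                dropped_rows.append((snp, "palindromic"))
                continue
            if palindrome_policy == "drop_ambiguous":
                if np.isnan(eaf_exp) or np.isnan(eaf_out):
                    dropped_rows.append((snp, "palindromic_ambiguous"))
                    continue
                if (
                    min(eaf_exp, 1 - eaf_exp) > ambiguous_maf
                    or min(eaf_out, 1 - eaf_out) > ambiguous_maf
                ):
                    dropped_rows.append((snp, "palindromic_ambiguous"))
                    continue
                # discordant frequencies indicate the outcome is on the
                # opposite strand: flip once more
                if (eaf_exp < 0.5) != (eaf_out < 0.5):
                    beta_out = -beta_out
                    eaf_out = 1.0 - eaf_out

        retained_rows.append(
            {
                "snp_id": snp,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "eaf_exp": eaf_exp,
                "n_exp": float(e["n"]),
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "eaf_out": eaf_out,
                "n_out": float(o["n"]),
                "palindromic": palindromic,
            }
        )

    if not retained_rows:
        warnings.warn(
            f"harmonize({exposure.trait_name}, {outcome.trait_name}): "
            "no SNPs retained",
            stacklevel=2,
        )
        table = pd.DataFrame(columns=HarmonizedTable.COLUMNS)
    else:
        table = pd.DataFrame(retained_rows, columns=HarmonizedTable.COLUMNS)
    dropped = pd.DataFrame(dropped_rows, columns=["snp_id", "reason"])
    return HarmonizedTable(table=table, dropped=dropped)
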