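"""Summary-statistics data model, IO, QC filters and four-way harmonization.

A :class:`SumstatsTable` holds per-SNP association records for one trait and
one analysis kind (GWAS additive effects, or GWIS SNP-by-modifier interaction
effects).  Four such tables — exposure GWAS, exposure GWIS, outcome GWAS,
outcome GWIS — are aligned to a common effect allele and SNP set by
:func:`harmonize`, producing the :class:`HarmonizedPanel` consumed by the
likelihood and inference machinery.

Tables are stored internally as :class:`pandas.DataFrame` with canonical
column names (``snp, chrom, pos, ea, oa, maf, beta, se, n, p``); readers
accept arbitrary delimited headers through a ``column_map``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "SumstatsRecord",
    "SumstatsTable",
    "HarmonizedPanel",
    "read_sumstats",
    "write_sumstats",
    "qc_filter",
    "harmonize",
    "DEFAULT_COLUMN_MAP",
]

#: canonical name -> default file header (GWAS-SSF-like dialect)
DEFAULT_COLUMN_MAP: Dict[str, str] = {
    "snp": "snp",
    "chrom": "chr",
    "pos": "pos",
    "ea": "ea",
    "oa": "oa",
    "maf": "eaf",
    "beta": "beta",
    "se": "se",
    "n": "n",
    "p": "p",
}

_MANDATORY = ("snp", "ea", "oa", "beta", "se")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SumstatsRecord:
    """One per-SNP association record."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float
    beta: float
    se: float
    n: float
    p: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: standard error must be > 0")
        if not self.effect_allele or not self.other_allele or self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must be non-empty and distinct")


class SumstatsTable:
    """Ordered, snp_id-unique collection of per-SNP records for one analysis.

    Parameters
    ----------
    df:
        Frame with canonical columns.  Mandatory: ``snp, ea, oa, beta, se``.
    trait_label:
        Free-text trait name.
    analysis_kind:
        ``"GWAS"`` or ``"GWIS"``.
    """

    def __init__(self, df: pd.DataFrame, trait_label: str = "", analysis_kind: str = "GWAS",
                 n_dropped: int = 0):
        if analysis_kind not in ("GWAS", "GWIS"):
            raise ValueError(f"analysis_kind must be GWAS or GWIS, got {analysis_kind!r}")
        missing = [c for c in _MANDATORY if c not in df.columns]
        if missing:
            raise KeyError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.reset_index(drop=True)
        dup = df["snp"].duplicated()
        if dup.any():
            logger.warning("%s: %d duplicate snp_id rows dropped (first occurrence kept)",
                           trait_label or analysis_kind, int(dup.sum()))
            df = df[~dup].reset_index(drop=True)
        if (df["se"] <= 0).any():
            bad = int((df["se"] <= 0).sum())
            raise ValueError(f"{bad} record(s) with non-positive standard error")
        if "p" not in df.columns or df["p"].isna().any():
            # two-sided normal P from beta/se where absent; needed by IV selection
            z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
            p = 2.0 * _stats.norm.sf(z)
            if "p" in df.columns:
                df["p"] = df["p"].fillna(pd.Series(p, index=df.index))
            else:
                df["p"] = p
        self.df = df
        self.trait_label = trait_label
        self.analysis_kind = analysis_kind
        self.n_dropped = n_dropped

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def from_arrays(cls, snp_ids: Sequence[str], beta: np.ndarray, se: np.ndarray, *,
                    n: Optional[np.ndarray] = None, maf: Optional[np.ndarray] = None,
                    chrom: str = "1", pos: Optional[np.ndarray] = None,
                    ea: str = "A", oa: str = "G",
                    trait_label: str = "", analysis_kind: str = "GWAS") -> "SumstatsTable":
        m = len(snp_ids)
        df = pd.DataFrame({
            "snp": list(snp_ids),
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100_000,
            "ea": ea,
            "oa": oa,
            "maf": maf if maf is not None else np.nan,
            "beta": np.asarray(beta, dtype=float),
            "se": np.asarray(se, dtype=float),
            "n": n if n is not None else np.nan,
        })
        return cls(df, trait_label=trait_label, analysis_kind=analysis_kind)

    # -- container protocol -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[SumstatsRecord]:
        for row in self.df.itertuples(index=False):
            yield SumstatsRecord(
                snp_id=row.snp, chrom=str(getattr(row, "chrom", "")),
                pos=int(getattr(row, "pos", 0) or 0),
                effect_allele=row.ea, other_allele=row.oa,
                maf=float(getattr(row, "maf", np.nan)),
                beta=float(row.beta), se=float(row.se),
                n=float(getattr(row, "n", np.nan)), p=float(row.p),
            )

    @property
    def records(self) -> list:
        return list(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SumstatsTable):
            return NotImplemented
        return (self.analysis_kind == other.analysis_kind
                and self.df[sorted(self.df.columns)].equals(other.df[sorted(other.df.columns)]))


def read_sumstats(path, column_map: Optional[Dict[str, str]] = None,
                  analysis_kind: str = "GWAS", trait_label: str = "",
                  sep: str = "\t") -> SumstatsTable:
    """Read a delimited summary-statistics table.

    ``column_map`` maps canonical names (``snp, chrom, pos, ea, oa, maf, beta,
    se, n, p``) to the file's headers; unmapped optional columns are filled
    with NA.  Rows whose ``beta`` or ``se`` fail to parse (or ``se <= 0``) are
    dropped and counted in ``table.n_dropped``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if raw.empty:
        raise ValueError(f"{path}: empty summary-statistics file")
    for canon in _MANDATORY:
        if cmap[canon] not in raw.columns:
            raise KeyError(f"{path}: mandatory column {cmap[canon]!r} (for {canon!r}) not found")
    df = pd.DataFrame({"snp": raw[cmap["snp"]].astype(str),
                       "ea": raw[cmap["ea"]].astype(str).str.upper(),
                       "oa": raw[cmap["oa"]].astype(str).str.upper()})
    for canon in ("chrom",):
        df[canon] = raw[cmap[canon]].astype(str) if cmap[canon] in raw.columns else ""
    for canon in ("pos", "maf", "beta", "se", "n", "p"):
        if cmap[canon] in raw.columns:
            df[canon] = pd.to_numeric(raw[cmap[canon]], errors="coerce")
        else:
            df[canon] = np.nan
    ok = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) with unparseable beta/se", path, n_dropped)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no parseable records")
    return SumstatsTable(df, trait_label=trait_label, analysis_kind=analysis_kind,
                         n_dropped=n_dropped)


def write_sumstats(table: SumstatsTable, path, sep: str = "\t") -> None:
    """Write a table back in the default dialect (inverse of :func:`read_sumstats`)."""
    out = table.df.rename(columns={v: k for k, v in {}.items()})
    rename = {"snp": "snp", "chrom": "chr", "pos": "pos", "ea": "ea", "oa": "oa",
              "maf": "eaf", "beta": "beta", "se": "se", "n": "n", "p": "p"}
    out = out.rename(columns=rename)
    cols = [c for c in ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "n", "p")
            if c in out.columns]
    out[cols].to_csv(path, sep=sep, index=False)


def qc_filter(table: SumstatsTable, maf_min: float = 0.05, z2_rule: bool = True) -> SumstatsTable:
    """Apply the standard marginal QC filters.

    Keeps records with ``maf >= maf_min`` and, when ``z2_rule`` is on, with
    ``(beta/se)^2 < max(80, n/1000)`` — the chi-square cap that guards against
    SNPs whose association is implausibly strong for the sample size.
    Order is preserved; the result is always a subset of the input.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    if maf_min is not None and maf_min > 0:
        if df["maf"].isna().any():
            raise ValueError("MAF filter enabled but maf missing for some records")
        maf = df["maf"].to_numpy(dtype=float)
        maf = np.minimum(maf, 1.0 - maf)
        keep &= maf >= maf_min
    if z2_rule:
        if "n" not in df.columns or df["n"].isna().any():
            raise ValueError("Z^2 filter enabled but n missing for some records")
        z2 = (df["beta"].to_numpy() / df["se"].to_numpy()) ** 2
        cap = np.maximum(80.0, df["n"].to_numpy(dtype=float) / 1000.0)
        keep &= z2 < cap
    out = SumstatsTable(df[keep].reset_index(drop=True), trait_label=table.trait_label,
                        analysis_kind=table.analysis_kind)
    out.n_dropped = int((~keep).sum())
    return out


@dataclass
class HarmonizedPanel:
    """SNP-aligned four-way summary statistics.

    One row per SNP: exposure GWAS effect ``gamma_G`` (SE ``s1``), exposure
    GWIS effect ``gamma_GI`` (SE ``s2``), outcome GWAS effect ``Gamma_G``
    (SE ``s3``), outcome GWIS effect ``Gamma_GI`` (SE ``s4``), all oriented to
    the exposure-GWAS effect allele.  ``p1``/``p2`` carry the exposure GWAS /
    GWIS P values used by instrument selection.
    """

    df: pd.DataFrame = field(repr=False)

    _VEC = ("gamma_G", "s1", "gamma_GI", "s2", "Gamma_G", "s3", "Gamma_GI", "s4")

    def __post_init__(self) -> None:
        missing = [c for c in ("snp",) + self._VEC if c not in self.df.columns]
        if missing:
            raise KeyError(f"harmonized panel missing column(s): {missing}")
        for c in ("s1", "s2", "s3", "s4"):
            if (self.df[c] <= 0).any():
                raise ValueError(f"non-positive standard error in {c}")
        self.df = self.df.reset_index(drop=True)

    # vector accessors -----------------------------------------------------------
    @property
    def snp_ids(self) -> list:
        return self.df["snp"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def __getattr__(self, name):
        if name in HarmonizedPanel._VEC:
            return self.df[name].to_numpy(dtype=float)
        raise AttributeError(name)

    @property
    def positions(self) -> Optional[np.ndarray]:
        return self.df["pos"].to_numpy(dtype=float) if "pos" in self.df.columns else None

    def subset(self, snp_ids: Sequence[str]) -> "HarmonizedPanel":
        idx = self.df.set_index("snp").loc[list(snp_ids)].reset_index()
        return HarmonizedPanel(idx)

    @classmethod
    def from_arrays(cls, snp_ids, gamma_G, s1, gamma_GI, s2, Gamma_G, s3, Gamma_GI, s4,
                    p1=None, p2=None, pos=None, chrom=None) -> "HarmonizedPanel":
        df = pd.DataFrame({"snp": list(snp_ids)})
        for name, arr in (("gamma_G", gamma_G), ("s1", s1), ("gamma_GI", gamma_GI), ("s2", s2),
                          ("Gamma_G", Gamma_G), ("s3", s3), ("Gamma_GI", Gamma_GI), ("s4", s4)):
            df[name] = np.asarray(arr, dtype=float)
        for k, (num, den) in (("p1", ("gamma_G", "s1")), ("p2", ("gamma_GI", "s2"))):
            given = p1 if k == "p1" else p2
            if given is not None:
                df[k] = np.asarray(given, dtype=float)
            else:
                df[k] = 2.0 * _stats.norm.sf(np.abs(df[num] / df[den]))
        if pos is not None:
            df["pos"] = np.asarray(pos)
        if chrom is not None:
            df["chrom"] = chrom
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "HarmonizedPanel":
        return cls(pd.read_csv(path, sep="\t"))


def _classify_alleles(ea_ref: str, oa_ref: str, ea: str, oa: str) -> Optional[bool]:
    """How do (ea, oa) relate to the reference pair?

    Returns ``False`` for same orientation, ``True`` for swapped (beta must be
    negated), ``None`` for an irreconcilable pair.  Strand flips (both alleles
    complemented) are folded into the same/swap classification.
    """
    if (ea, oa) == (ea_ref, oa_ref):
        return False
    if (ea, oa) == (oa_ref, ea_ref):
        return True
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if cea is None or coa is None:
        return None
    if (cea, coa) == (ea_ref, oa_ref):
        return False
    if (cea, coa) == (oa_ref, ea_ref):
        return True
    return None


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(exp_gwas: SumstatsTable, exp_gwis: SumstatsTable,
              out_gwas: SumstatsTable, out_gwis: SumstatsTable,
              drop_palindromic: bool = True) -> HarmonizedPanel:
    """Align the four summary-statistics tables to a common effect allele.

    The exposure-GWAS effect allele is the reference orientation.  For every
    SNP in the four-way intersection, effects reported for the opposite allele
    are negated (and MAF replaced by 1 - MAF); strand flips are resolved via
    complements.  Strand-ambiguous A/T and C/G SNPs are dropped by default
    because their orientation cannot be established from alleles alone.
    SNPs with irreconcilable allele pairs are dropped with a warning.
    """
    tables = {"exp_gwas": exp_gwas, "exp_gwis": exp_gwis,
              "out_gwas": out_gwas, "out_gwis": out_gwis}
    common = exp_gwas.df["snp"]
    common_set = set(common)
    for t in (exp_gwis, out_gwas, out_gwis):
        common_set &= set(t.df["snp"])
    if not common_set:
        raise ValueError("no SNPs shared by all four summary-statistics tables")
    # preserve exposure-GWAS order
    snp_order = [s for s in common if s in common_set]

    frames = {k: t.df.set_index("snp").loc[snp_order] for k, t in tables.items()}
    ref = frames["exp_gwas"]

    keep = np.ones(len(snp_order), dtype=bool)
    aligned: Dict[str, pd.DataFrame] = {}
    for key, fr in frames.items():
        fr = fr.copy()
        if key == "exp_gwas":
            if drop_palindromic:
                pal = np.array([_is_palindromic(e, o) for e, o in zip(fr["ea"], fr["oa"])])
                keep &= ~pal
            aligned[key] = fr
            continue
        flips = np.zeros(len(fr), dtype=bool)
        for i, (snp, ea, oa) in enumerate(zip(snp_order, fr["ea"], fr["oa"])):
            if drop_palindromic and _is_palindromic(ea, oa):
                keep[i] = False
                continue
            cls = _classify_alleles(ref["ea"].iloc[i], ref["oa"].iloc[i], ea, oa)
            if cls is None:
                logger.warning("harmonize: %s alleles %s/%s irreconcilable with reference %s/%s; dropped",
                               snp, ea, oa, ref["ea"].iloc[i], ref["oa"].iloc[i])
                keep[i] = False
            else:
                flips[i] = cls
        fr.loc[flips, "beta"] = -fr.loc[flips, "beta"]
        if "maf" in fr.columns:
            fr.loc[flips, "maf"] = 1.0 - fr.loc[flips, "maf"]
        fr["ea"] = ref["ea"].to_numpy()
        fr["oa"] = ref["oa"].to_numpy()
        aligned[key] = fr
    if not keep.any():
        raise ValueError("no SNPs left after harmonization")

    sel = np.asarray(keep)
    snps = [s for s, k in zip(snp_order, sel) if k]
    e1, e2 = aligned["exp_gwas"][sel], aligned["exp_gwis"][sel]
    o1, o2 = aligned["out_gwas"][sel], aligned["out_gwis"][sel]
    panel = HarmonizedPanel.from_arrays(
        snps,
        e1["beta"].to_numpy(), e1["se"].to_numpy(),
        e2["beta"].to_numpy(), e2["se"].to_numpy(),
        o1["beta"].to_numpy(), o1["se"].to_numpy(),
        o2["beta"].to_numpy(), o2["se"].to_numpy(),
        p1=e1["p"].to_numpy() if "p" in e1.columns else None,
        p2=e2["p"].to_numpy() if "p" in e2.columns else None,
        pos=e1["pos"].to_numpy() if "pos" in e1.columns else None,
        chrom=e1["chrom"].to_numpy() if "chrom" in e1.columns else None,
    )
    return panel


def write_qc_sidecar(path, **counts) -> None:
    """Record QC drop counts next to an output file."""
    with open(path, "w") as fh:
        json.dump(counts, fh, indent=2)
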