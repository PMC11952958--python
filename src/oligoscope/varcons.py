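"""Per-residue tracks, missense variants and the domain depletion statistic.

The central quantity is the V_d/V_p ratio: the density of unique missense
variants inside a domain divided by the density over the whole protein.
Values below 1 indicate the domain is depleted of standing variation relative
to the protein as a whole, a population-genetic signature of constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ResidueTrack:
    """Per-residue values (conservation grade, probability, count) for one protein."""

    protein: str
    length: int
    values: np.ndarray           # float, NaN = missing, index 0 == residue 1
    semantics: str = "score"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("protein length must be positive")
        self.values = np.asarray(self.values, float)
        if len(self.values) != self.length:
            raise ValueError("track length mismatch")


@dataclass
class VariantSet:
    """Missense variants for one protein: (position, change, flags, source)."""

    protein: str
    table: pd.DataFrame          # columns: position, change, flags (frozenset), source

    def __post_init__(self):
        needed = {"position", "change", "flags", "source"}
        if not needed.issubset(self.table.columns):
            raise ValueError(f"variant table needs columns {sorted(needed)}")

    @classmethod
    def from_records(cls, protein, records):
        rows = [{"position": int(p), "change": str(c),
                 "flags": frozenset(f), "source": str(s)}
                for p, c, f, s in records]
        return cls(protein, pd.DataFrame(rows, columns=["position", "change", "flags", "source"]))

    def __len__(self):
        return len(self.table)


@dataclass
class DomainAnnotation:
    """Named 1-based inclusive residue intervals."""

    intervals: list  # (label, start, end)

    def __post_init__(self):
        labels = [l for l, _, _ in self.intervals]
        if len(set(labels)) != len(labels):
            raise ValueError("domain labels must be unique")
        for label, s, e in self.intervals:
            if not (1 <= s <= e):
                raise ValueError(f"bad interval {label}: [{s}, {e}]")

    def membership(self, length: int) -> pd.DataFrame:
        pos = np.arange(1, length + 1)
        df = pd.DataFrame({"position": pos})
        for label, s, e in self.intervals:
            df[label] = (pos >= s) & (pos <= e)
        return df


def filter_variants(variants: VariantSet,
                    exclude: set = frozenset({"pathogenic", "clinvar"})):
    """Drop variants carrying any excluded flag; report removals per flag.

    Idempotent; never increases the variant count.
    """
    exclude = frozenset(exclude)
    keep = variants.table["flags"].apply(lambda f: not (frozenset(f) & exclude))
    removed_log = {}
    for flag in sorted(exclude):
        removed_log[flag] = int(
            variants.table.loc[~keep, "flags"].apply(lambda f: flag in f).sum())
    out = VariantSet(variants.protein, variants.table[keep].reset_index(drop=True))
    return out, removed_log


@dataclass
class DepletionResult:
    ratio: float
    v_d: float                   # variants per residue in the domain
    v_p: float                   # variants per residue over the protein
    n_domain: int
    n_total: int
    ok: bool = True
    message: str = ""


def depletion_ratio(variants: VariantSet, domain: tuple, protein_length: int,
                    unit: str = "change") -> DepletionResult:
    """V_d/V_p: domain variant density over whole-protein variant density.

    ``unit='change'`` counts unique (position, amino-acid change) pairs
    (multiple alleles at one position count separately); ``unit='position'``
    counts unique positions.
    """
    label, start, end = domain
    if not (1 <= start <= end <= protein_length):
        raise ValueError(f"domain {label} [{start},{end}] outside protein 1..{protein_length}")
    t = variants.table
    if unit == "change":
        uniq = t.drop_duplicates(["position", "change"])
    elif unit == "position":
        uniq = t.drop_duplicates(["position"])
    else:
        raise ValueError("unit must be 'change' or 'position'")
    n_total = len(uniq)
    if n_total == 0:
        return DepletionResult(np.nan, np.nan, np.nan, 0, 0, ok=False,
                               message="no variants on the protein; ratio undefined")
    in_dom = uniq[(uniq["position"] >= start) & (uniq["position"] <= end)]
    v_d = len(in_dom) / (end - start + 1)
    v_p = n_total / protein_length
    return DepletionResult(ratio=v_d / v_p, v_d=v_d, v_p=v_p,
                           n_domain=len(in_dom), n_total=n_total)


def combine_tracks(tracks: list[ResidueTrack], variants: VariantSet | None,
                   domains: DomainAnnotation | None) -> pd.DataFrame:
    """One row per residue with every track value, variant count and domain flags."""
    if not tracks and variants is None:
        raise ValueError("nothing to combine")
    lengths = {t.length for t in tracks}
    if len(lengths) > 1:
        names = {t.semantics: t.length for t in tracks}
        raise ValueError(f"track length mismatch: {names}")
    length = lengths.pop() if lengths else int(variants.table["position"].max())
    df = pd.DataFrame({"position": np.arange(1, length + 1)})
    for t in tracks:
        df[t.semantics] = t.values
    counts = np.zeros(length, int)
    if variants is not None:
        vc = variants.table["position"].value_counts()
        for pos, c in vc.items():
            if 1 <= pos <= length:
                counts[pos - 1] = c
    df["variant_count"] = counts
    if domains is not None:
        mem = domains.membership(length)
        for col in mem.columns:
            if col != "position":
                df[col] = mem[col]
    return df


def read_track(path, protein: str, length: int, semantics: str = "score") -> ResidueTrack:
    """Read a 2-column (position, value) TSV into a ResidueTrack."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     names=["position", "value"], header=None)
    vals = np.full(length, np.nan)
    for _, row in df.iterrows():
        p = int(row["position"])
        if 1 <= p <= length:
            vals[p - 1] = float(row["value"])
    return ResidueTrack(protein, length, vals, semantics)


def read_variants(path, protein: str, schema: dict | None = None) -> VariantSet:
    """Read a variant TSV (position, change, flags, source columns mappable)."""
    schema = schema or {"position": "position", "change": "change",
                        "flags": "flags", "source": "source"}
    df = pd.read_csv(path, sep=None, engine="python")
    recs = []
    for _, row in df.iterrows():
        flags = row.get(schema["flags"], "")
        flagset = frozenset(str(flags).split(";")) - {"", "nan"} if pd.notna(flags) else frozenset()
        recs.append((int(row[schema["position"]]), str(row.get(schema["change"], "?")),
                     flagset, str(row.get(schema["source"], ""))))
    return VariantSet.from_records(protein, recs)
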