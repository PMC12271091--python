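"""Reading, harmonization and QC of GWAS summary statistics.

All downstream estimation consumes a :class:`HarmonizedPanel`: per-trait
Z-scores and sample sizes aligned to a shared variant index with a single
effect-allele convention (that of the first trait supplied).
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SumstatsTable",
    "HarmonizedPanel",
    "SumstatsError",
    "read_sumstats",
    "harmonize",
    "qc_filter",
    "default_chisq_max",
    "write_panel",
    "read_panel",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: header aliases recognised without an explicit column_map
_DEFAULT_ALIASES = {
    "variant_id": ("SNP", "RSID", "ID", "VARIANT_ID", "MARKERNAME"),
    "chrom": ("CHR", "CHROM", "CHROMOSOME"),
    "pos": ("BP", "POS", "POSITION"),
    "allele_effect": ("A1", "EFFECT_ALLELE", "ALLELE1", "EA"),
    "allele_other": ("A2", "OTHER_ALLELE", "ALLELE2", "OA", "NEA"),
    "z": ("Z", "ZSCORE", "Z_SCORE"),
    "beta": ("BETA", "B", "EFFECT", "LOG_ODDS"),
    "se": ("SE", "STDERR"),
    "n": ("N", "NEFF", "N_EFF", "SAMPLE_SIZE"),
    "freq_effect": ("FRQ", "FREQ", "EAF", "MAF", "AF"),
    "pvalue": ("P", "PVAL", "P_VALUE", "PVALUE"),
}

_MANDATORY = ("variant_id", "allele_effect", "allele_other", "n")


class SumstatsError(ValueError):
    """Raised for malformed or inconsistent summary-statistics input."""


@dataclass
class SumstatsTable:
    """Per-variant association results for one trait.

    ``df`` columns: variant_id, chrom, pos, allele_effect, allele_other,
    z, n and optionally freq_effect, pvalue.  Row order is preserved from
    the source file.
    """

    trait_label: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise SumstatsError(
                f"trait {self.trait_label!r}: duplicated variant_id values: "
                f"{sorted(set(dup))[:10]}"
            )
        z = self.df["z"].to_numpy(float)
        if not np.all(np.isfinite(z)):
            bad = self.df["variant_id"][~np.isfinite(z)].iloc[0]
            raise SumstatsError(f"trait {self.trait_label!r}: non-finite z at {bad}")
        n = self.df["n"].to_numpy(float)
        if not np.all(n > 0):
            bad = self.df["variant_id"][~(n > 0)].iloc[0]
            raise SumstatsError(f"trait {self.trait_label!r}: non-positive n at {bad}")
        same = self.df["allele_effect"].str.upper() == self.df["allele_other"].str.upper()
        if same.any():
            bad = self.df["variant_id"][same].iloc[0]
            raise SumstatsError(
                f"trait {self.trait_label!r}: identical alleles at {bad}"
            )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class HarmonizedPanel:
    """Multi-trait Z/N arrays on a shared variant index.

    Effect alleles follow the first trait's convention; ``z`` and ``n`` are
    (n_variants, n_traits) arrays in ``traits`` order.
    """

    traits: list[str]
    variants: pd.DataFrame  # variant_id, chrom, pos, allele_effect, allele_other
    z: np.ndarray
    n: np.ndarray
    freq: np.ndarray  # (n_variants, n_traits), NaN where unavailable
    sign_flips: dict[str, int] = field(default_factory=dict)
    dropped_ambiguous: int = 0
    dropped_irreconcilable: int = 0

    def __post_init__(self) -> None:
        m, k = self.z.shape
        assert self.n.shape == (m, k) and self.freq.shape == (m, k)
        assert len(self.variants) == m and len(self.traits) == k

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def to_tables(self) -> list[SumstatsTable]:
        """Decompose back into per-trait tables (inverse of harmonize)."""
        out = []
        for t, label in enumerate(self.traits):
            df = self.variants.copy()
            df["z"] = self.z[:, t]
            df["n"] = self.n[:, t]
            if np.isfinite(self.freq[:, t]).any():
                df["freq_effect"] = self.freq[:, t]
            out.append(SumstatsTable(label, df.reset_index(drop=True)))
        return out

    def subset(self, keep: np.ndarray) -> "HarmonizedPanel":
        """Row-subset by boolean mask, preserving provenance counters."""
        return HarmonizedPanel(
            traits=list(self.traits),
            variants=self.variants.loc[keep].reset_index(drop=True),
            z=self.z[keep],
            n=self.n[keep],
            freq=self.freq[keep],
            sign_flips=dict(self.sign_flips),
            dropped_ambiguous=self.dropped_ambiguous,
            dropped_irreconcilable=self.dropped_irreconcilable,
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_label: str | None = None,
) -> SumstatsTable:
    """Read one whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    path:
        Delimited text file with a header row (gzip-transparent).
    column_map:
        Mapping from canonical field names (``variant_id``, ``allele_effect``,
        ``allele_other``, ``z`` or ``beta``+``se``, ``n``, optionally
        ``chrom``, ``pos``, ``freq_effect``, ``pvalue``) to the file's
        headers.  When omitted, common header aliases are recognised.
    trait_label:
        Defaults to the file stem.

    ``z`` is computed as ``beta/se`` when absent from the file.
    """
    path = Path(path)
    if trait_label is None:
        trait_label = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=r"\s+", dtype=str)
    raw.columns = [c.strip() for c in raw.columns]

    if column_map is None:
        upper = {c.upper(): c for c in raw.columns}
        column_map = {}
        for canon, aliases in _DEFAULT_ALIASES.items():
            for alias in aliases:
                if alias in upper:
                    column_map[canon] = upper[alias]
                    break
    missing = [c for c in _MANDATORY if c not in column_map]
    if "z" not in column_map and not {"beta", "se"} <= column_map.keys():
        missing.append("z (or beta and se)")
    if missing:
        raise SumstatsError(
            f"{path}: could not resolve mandatory column(s): {', '.join(missing)}"
        )
    for canon, col in column_map.items():
        if col not in raw.columns:
            raise SumstatsError(f"{path}: column_map names absent header {col!r}")

    df = pd.DataFrame({"variant_id": raw[column_map["variant_id"]].str.strip()})
    for canon in ("chrom", "pos"):
        if canon in column_map:
            df[canon] = raw[column_map[canon]]
    for canon in ("allele_effect", "allele_other"):
        df[canon] = raw[column_map[canon]].str.strip().str.upper()

    def _numeric(canon: str) -> np.ndarray:
        vals = pd.to_numeric(raw[column_map[canon]], errors="coerce")
        bad = vals.isna() & raw[column_map[canon]].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad)[0]) + 2
            raise SumstatsError(
                f"{path}: non-numeric {canon} value "
                f"{raw[column_map[canon]][bad].iloc[0]!r} on line {line}"
            )
        return vals.to_numpy(float)

    if "z" in column_map:
        df["z"] = _numeric("z")
    else:
        beta, se = _numeric("beta"), _numeric("se")
        if np.any(se <= 0):
            line = int(np.flatnonzero(se <= 0)[0]) + 2
            raise SumstatsError(f"{path}: non-positive SE on line {line}")
        df["z"] = beta / se
    df["n"] = _numeric("n")
    if "pos" in df.columns:
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    for canon in ("freq_effect", "pvalue"):
        if canon in column_map:
            df[canon] = _numeric(canon)
    return SumstatsTable(trait_label, df)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2


def _complement(a: str) -> str:
    return "".join(_COMPLEMENT.get(b, "?") for b in a)


def harmonize(tables: list[SumstatsTable]) -> HarmonizedPanel:
    """Align ≥2 trait tables onto their shared variant set.

    The first table fixes the effect-allele convention.  For every other
    table, a variant whose alleles are swapped (or strand-flipped, or both)
    relative to the reference has its Z-score sign adjusted accordingly;
    strand-ambiguous variants (A/T, C/G) are dropped everywhere; variants
    whose alleles cannot be reconciled are dropped and counted.
    """
    if len(tables) < 2:
        raise SumstatsError("harmonize requires at least 2 tables")
    labels = [t.trait_label for t in tables]
    if len(set(labels)) != len(labels):
        raise SumstatsError(f"duplicate trait labels: {labels}")

    shared = set(tables[0].df["variant_id"])
    for t in tables[1:]:
        shared &= set(t.df["variant_id"])
    if not shared:
        raise SumstatsError("empty variant intersection across traits")

    ref = tables[0].df
    ref = ref[ref["variant_id"].isin(shared)].reset_index(drop=True)
    order = ref["variant_id"].to_numpy()
    e1 = ref["allele_effect"].to_numpy()
    e2 = ref["allele_other"].to_numpy()

    m, k = len(order), len(tables)
    z = np.full((m, k), np.nan)
    n = np.full((m, k), np.nan)
    freq = np.full((m, k), np.nan)
    keep = np.ones(m, bool)
    ambiguous = np.zeros(m, bool)
    sign_flips = {lab: 0 for lab in labels}
    flip_masks = np.zeros((m, k), bool)

    for t, tab in enumerate(tables):
        df = tab.df.set_index("variant_id").loc[order]
        a1 = df["allele_effect"].to_numpy()
        a2 = df["allele_other"].to_numpy()
        amb = np.array([_is_ambiguous(x, y) for x, y in zip(a1, a2)])
        ambiguous |= amb
        match = (a1 == e1) & (a2 == e2)
        swap = (a1 == e2) & (a2 == e1)
        c1 = np.array([_complement(x) for x in a1])
        c2 = np.array([_complement(x) for x in a2])
        cmatch = (c1 == e1) & (c2 == e2) & ~match & ~swap
        cswap = (c1 == e2) & (c2 == e1) & ~match & ~swap
        ok = match | swap | cmatch | cswap
        keep &= ok
        flip = swap | cswap
        flip_masks[:, t] = flip
        zt = df["z"].to_numpy(float)
        z[:, t] = np.where(flip, -zt, zt)
        n[:, t] = df["n"].to_numpy(float)
        if "freq_effect" in df.columns:
            f = df["freq_effect"].to_numpy(float)
            freq[:, t] = np.where(flip, 1.0 - f, f)

    final = keep & ~ambiguous
    for t, lab in enumerate(labels):
        sign_flips[lab] = int(flip_masks[final, t].sum())
    return HarmonizedPanel(
        traits=labels,
        variants=ref.loc[final, ["variant_id"] + [c for c in ("chrom", "pos") if c in ref]
                         + ["allele_effect", "allele_other"]].reset_index(drop=True),
        z=z[final],
        n=n[final],
        freq=freq[final],
        sign_flips=sign_flips,
        dropped_ambiguous=int(ambiguous.sum()),
        dropped_irreconcilable=int((~keep & ~ambiguous).sum()),
    )


def default_chisq_max(median_n: float) -> float:
    """Conventional outlier threshold max(80, 0.001 * median N)."""
    return max(80.0, 0.001 * float(median_n))


def qc_filter(
    panel: HarmonizedPanel,
    maf_min: float = 0.0,
    chisq_max: float | None = None,
) -> HarmonizedPanel:
    """Drop variants by minor-allele frequency and extreme association.

    A variant is removed if any trait's available frequency lies outside
    ``[maf_min, 1 - maf_min]``, or (when ``chisq_max`` is set) if any
    trait's z² exceeds ``chisq_max``.  ``chisq_max=None`` disables the
    chi-square filter entirely.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    keep = np.ones(panel.n_variants, bool)
    if maf_min > 0:
        with np.errstate(invalid="ignore"):
            bad = (panel.freq < maf_min) | (panel.freq > 1 - maf_min)
        keep &= ~np.nan_to_num(bad, nan=False).any(axis=1)
    if chisq_max is not None:
        keep &= ~(panel.z**2 > chisq_max).any(axis=1)
    if not keep.any():
        raise SumstatsError("qc_filter removed all variants")
    return panel.subset(keep)


def write_panel(panel: HarmonizedPanel, prefix: str | Path) -> None:
    """Serialize panel as <prefix>.tsv (wide table) + <prefix>.json provenance."""
    prefix = Path(prefix)
    wide = panel.variants.copy()
    for t, lab in enumerate(panel.traits):
        wide[f"z.{lab}"] = panel.z[:, t]
        wide[f"n.{lab}"] = panel.n[:, t]
        wide[f"freq.{lab}"] = panel.freq[:, t]
    wide.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    meta = {
        "traits": panel.traits,
        "n_variants": panel.n_variants,
        "sign_flips": panel.sign_flips,
        "dropped_ambiguous": panel.dropped_ambiguous,
        "dropped_irreconcilable": panel.dropped_irreconcilable,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_panel(prefix: str | Path) -> HarmonizedPanel:
    prefix = Path(prefix)
    wide = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", dtype={"variant_id": str})
    meta = json.loads(prefix.with_suffix(".json").read_text())
    traits = meta["traits"]
    var_cols = [c for c in wide.columns if "." not in c]
    z = np.column_stack([wide[f"z.{t}"] for t in traits])
    n = np.column_stack([wide[f"n.{t}"] for t in traits])
    freq = np.column_stack([wide[f"freq.{t}"] for t in traits])
    return HarmonizedPanel(
        traits=traits,
        variants=wide[var_cols],
        z=z,
        n=n,
        freq=freq,
        sign_flips=meta["sign_flips"],
        dropped_ambiguous=meta["dropped_ambiguous"],
        dropped_irreconcilable=meta["dropped_irreconcilable"],
    )
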