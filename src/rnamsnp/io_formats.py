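"""Readers and writers for every table the pipeline touches.

All tables are plain delimited text (TSV by default) and are represented in
memory as :class:`pandas.DataFrame` objects with canonical column names.
Readers validate hard invariants row by row: rows that violate them are
rejected (never silently fixed) and the rejection count plus row-numbered
diagnostics are stored in ``df.attrs``.  For every reader,
``accepted + rejected == input rows``.

Canonical schemas
-----------------
GWAS / association table
    ``rsid chrom pos effect_allele other_allele eaf beta se pvalue n``
    (``eaf`` and ``n`` may be missing).
RNA-modification catalogue (RMVar-dump style; the canonical 7 columns are a
package convention, a ``column_map`` accommodates other dialects)
    ``rsid mod_type confidence effect gene gene_type region``
QTL table
    ``rsid target_id target_chrom target_tss beta se pvalue tissue_or_study``
LD panel
    either a dosage matrix (rows = individuals, columns = rsids, dosages
    0/1/2) or a long correlation table ``rsid_a rsid_b r``.
Gene sets
    standard GMT (name, description, genes, tab-separated).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SchemaError",
    "MOD_TYPES",
    "CONFIDENCE_LEVELS",
    "GWAS_COLUMNS",
    "QTL_COLUMNS",
    "CATALOGUE_COLUMNS",
    "GeneSetCollection",
    "LdPanel",
    "read_gwas",
    "read_qtl",
    "read_rnam_catalogue",
    "read_gmt",
    "write_gmt",
    "read_ld_panel",
    "write_results",
    "read_table",
]


class SchemaError(ValueError):
    """A mandatory column is missing or a file is structurally unreadable."""


#: The nine RNA-modification types of the catalogue vocabulary.
MOD_TYPES = (
    "m6A",
    "m6Am",
    "m1A",
    "2'-O-Me",
    "m5C",
    "m5U",
    "m7G",
    "A-to-I",
    "pseudouridine",
)

CONFIDENCE_LEVELS = ("high", "medium", "low")
_CONFIDENCE_RANK = {"high": 0, "medium": 1, "low": 2}

EFFECT_LEVELS = ("gain", "loss")
GENE_TYPES = ("protein_coding", "noncoding")
REGIONS = ("exonic", "3'UTR", "5'UTR", "intronic", "other")

GWAS_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
_GWAS_MANDATORY = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue")

QTL_COLUMNS = (
    "rsid",
    "target_id",
    "target_chrom",
    "target_tss",
    "beta",
    "se",
    "pvalue",
    "tissue_or_study",
)
_QTL_MANDATORY = ("rsid", "target_id", "beta", "se", "pvalue")

CATALOGUE_COLUMNS = (
    "rsid",
    "mod_type",
    "confidence",
    "effect",
    "gene",
    "gene_type",
    "region",
)

_P_FLOOR = 1e-300


def _rename(df: pd.DataFrame, column_map: dict | None, mandatory, what: str) -> pd.DataFrame:
    """Apply a canonical<-source column map and check mandatory columns."""
    if column_map:
        inverse = {src: canon for canon, src in column_map.items()}
        missing_src = [s for s in inverse if s not in df.columns]
        if missing_src:
            raise SchemaError(f"{what}: column_map names absent source columns {missing_src}")
        df = df.rename(columns=inverse)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")
    return df


def _finish(df: pd.DataFrame, rejections: list, n_input: int) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    df.attrs["n_input"] = n_input
    df.attrs["n_rejected"] = len(rejections)
    df.attrs["rejections"] = rejections
    if rejections:
        warnings.warn(
            f"rejected {len(rejections)}/{n_input} rows; first: row {rejections[0][0]}: "
            f"{rejections[0][1]}",
            stacklevel=3,
        )
    return df


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited text file with a header row, keeping strings as strings."""
    return pd.read_csv(path, sep=sep, dtype={"rsid": str, "chrom": str}, na_values=["NA", ""])


def read_gwas(path, column_map: dict | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read GWAS/association summary statistics into the canonical schema.

    Parameters
    ----------
    path
        Delimited text file with a header line.
    column_map
        Mapping from canonical field name to the source column name, e.g.
        ``{"rsid": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
        "other_allele": "A2", "eaf": "FRQ", "beta": "BETA", "se": "SE",
        "pvalue": "P"}``.  Omit for files already in canonical form.
    sep
        Field delimiter (default tab).

    Rows with nonpositive SE, identical alleles, non-ACGT alleles, invalid
    position, allele frequency outside [0, 1] or p-value outside (0, 1] are
    rejected; counts and diagnostics end up in ``df.attrs``.  ``p == 0`` is
    clamped to 1e-300 with a warning rather than rejected.  A p-value that is
    inconsistent with ``|beta/se|`` under the two-sided normal approximation
    by more than a factor of 10 triggers a warning only.
    """
    raw = read_table(path, sep=sep)
    raw = _rename(raw, column_map, _GWAS_MANDATORY, "GWAS table")
    for col in GWAS_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    raw = raw[list(GWAS_COLUMNS)]
    return _validate_association(raw)


def _validate_association(raw: pd.DataFrame) -> pd.DataFrame:
    n_input = len(raw)
    rejections: list[tuple[int, str]] = []
    rows = []
    n_clamped = 0
    for i, row in enumerate(raw.itertuples(index=False)):
        rec = row._asdict()
        try:
            rec["rsid"] = str(rec["rsid"])
            rec["chrom"] = str(rec["chrom"])
            rec["pos"] = int(rec["pos"])
            if rec["pos"] < 1:
                raise ValueError(f"position {rec['pos']} < 1")
            ea = str(rec["effect_allele"]).upper()
            oa = str(rec["other_allele"]).upper()
            for a in (ea, oa):
                if not a or set(a) - set("ACGT"):
                    raise ValueError(f"allele {a!r} not an A/C/G/T string")
            if ea == oa:
                raise ValueError(f"effect allele equals other allele ({ea})")
            rec["effect_allele"], rec["other_allele"] = ea, oa
            se = float(rec["se"])
            if not np.isfinite(se) or se <= 0:
                raise ValueError(f"nonpositive or missing SE ({rec['se']})")
            rec["se"] = se
            rec["beta"] = float(rec["beta"])
            if not np.isfinite(rec["beta"]):
                raise ValueError("missing beta")
            p = float(rec["pvalue"])
            if p == 0.0:
                p = _P_FLOOR
                n_clamped += 1
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value {rec['pvalue']} outside (0, 1]")
            rec["pvalue"] = p
            eaf = rec["eaf"]
            if pd.notna(eaf):
                eaf = float(eaf)
                if not (0.0 <= eaf <= 1.0):
                    raise ValueError(f"eaf {eaf} outside [0, 1]")
                rec["eaf"] = eaf
            else:
                rec["eaf"] = np.nan
            rec["n"] = int(rec["n"]) if pd.notna(rec["n"]) else np.nan
        except (ValueError, TypeError) as exc:
            rejections.append((i + 1, str(exc)))
            continue
        # soft check: p consistent with |beta/se| under the normal approximation
        p_expected = 2.0 * stats.norm.sf(abs(rec["beta"] / rec["se"]))
        if p_expected > 0 and not (0.1 <= rec["pvalue"] / max(p_expected, _P_FLOOR) <= 10.0):
            warnings.warn(
                f"row {i + 1} ({rec['rsid']}): p={rec['pvalue']:.3g} inconsistent with "
                f"|beta/se| (expected ~{p_expected:.3g})",
                stacklevel=3,
            )
        rows.append(rec)
    if n_clamped:
        warnings.warn(f"{n_clamped} p-value(s) of 0 clamped to {_P_FLOOR}", stacklevel=3)
    out = pd.DataFrame(rows, columns=list(GWAS_COLUMNS))
    return _finish(out, rejections, n_input)


def read_qtl(path, column_map: dict | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read a cis-eQTL/pQTL summary table into the canonical QTL schema."""
    raw = read_table(path, sep=sep)
    raw = _rename(raw, column_map, _QTL_MANDATORY, "QTL table")
    for col in QTL_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    raw = raw[list(QTL_COLUMNS)]
    n_input = len(raw)
    rejections: list[tuple[int, str]] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        rec = row._asdict()
        try:
            rec["rsid"] = str(rec["rsid"])
            rec["target_id"] = str(rec["target_id"])
            se = float(rec["se"])
            if not np.isfinite(se) or se <= 0:
                raise ValueError(f"nonpositive or missing SE ({rec['se']})")
            rec["se"] = se
            rec["beta"] = float(rec["beta"])
            p = float(rec["pvalue"])
            if p == 0.0:
                p = _P_FLOOR
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value {rec['pvalue']} outside (0, 1]")
            rec["pvalue"] = p
            rec["target_chrom"] = str(rec["target_chrom"]) if pd.notna(rec["target_chrom"]) else np.nan
            rec["target_tss"] = int(rec["target_tss"]) if pd.notna(rec["target_tss"]) else np.nan
            rec["tissue_or_study"] = (
                str(rec["tissue_or_study"]) if pd.notna(rec["tissue_or_study"]) else "unknown"
            )
        except (ValueError, TypeError) as exc:
            rejections.append((i + 1, str(exc)))
            continue
        rows.append(rec)
    out = pd.DataFrame(rows, columns=list(QTL_COLUMNS))
    return _finish(out, rejections, n_input)


def read_rnam_catalogue(path, column_map: dict | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read an RNA-modification SNP catalogue (RMVar-dump style).

    Extra columns are tolerated and dropped.  Rows with a modification type
    outside the nine-type vocabulary are rejected with a message listing the
    allowed tokens.  Duplicate ``(rsid, mod_type)`` pairs are collapsed,
    keeping the highest confidence tier.
    """
    raw = read_table(path, sep=sep)
    raw = _rename(raw, column_map, ("rsid", "mod_type"), "RNAm catalogue")
    for col in CATALOGUE_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    raw = raw[list(CATALOGUE_COLUMNS)]
    n_input = len(raw)
    rejections: list[tuple[int, str]] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        rec = row._asdict()
        try:
            rec["rsid"] = str(rec["rsid"])
            mt = str(rec["mod_type"])
            if mt not in MOD_TYPES:
                raise ValueError(
                    f"unknown mod_type {mt!r}; allowed: {', '.join(MOD_TYPES)}"
                )
            conf = str(rec["confidence"]).lower() if pd.notna(rec["confidence"]) else "low"
            if conf not in CONFIDENCE_LEVELS:
                raise ValueError(f"unknown confidence {rec['confidence']!r}; allowed: {CONFIDENCE_LEVELS}")
            rec["confidence"] = conf
            eff = str(rec["effect"]).lower() if pd.notna(rec["effect"]) else "loss"
            if eff not in EFFECT_LEVELS:
                raise ValueError(f"unknown effect {rec['effect']!r}; allowed: {EFFECT_LEVELS}")
            rec["effect"] = eff
            rec["gene"] = str(rec["gene"]) if pd.notna(rec["gene"]) else np.nan
            gt = rec["gene_type"]
            if pd.notna(gt):
                gt = str(gt)
                if gt not in GENE_TYPES:
                    raise ValueError(f"unknown gene_type {gt!r}; allowed: {GENE_TYPES}")
                rec["gene_type"] = gt
            else:
                rec["gene_type"] = np.nan
            reg = rec["region"]
            if pd.notna(reg):
                reg = str(reg)
                if reg not in REGIONS:
                    raise ValueError(f"unknown region {reg!r}; allowed: {REGIONS}")
                rec["region"] = reg
            else:
                rec["region"] = "other"
        except (ValueError, TypeError) as exc:
            rejections.append((i + 1, str(exc)))
            continue
        rows.append(rec)
    out = pd.DataFrame(rows, columns=list(CATALOGUE_COLUMNS))
    if len(out):
        out["_rank"] = out["confidence"].map(_CONFIDENCE_RANK)
        out = (
            out.sort_values(["rsid", "mod_type", "_rank"], kind="mergesort")
            .drop_duplicates(["rsid", "mod_type"], keep="first")
            .drop(columns="_rank")
        )
    return _finish(out, rejections, n_input)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional explicit universe.

    Gene symbols are uppercased and deduplicated; set names are unique.
    """

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)
    universe: frozenset | None = None

    def __post_init__(self):
        self.sets = {name: frozenset(g.upper() for g in genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def all_genes(self) -> frozenset:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; lines with fewer than 3 fields are dropped with a warning."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                n_bad += 1
                warnings.warn(f"GMT line {lineno}: fewer than 3 fields, skipped", stacklevel=2)
                continue
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets[name] = frozenset(g.upper() for g in genes)
            descriptions[name] = desc
    coll = GeneSetCollection(sets=sets, descriptions=descriptions)
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------


class LdPanel:
    """Pairwise allelic correlation provider.

    Backed either by a dosage matrix (individuals x SNPs, values 0/1/2) from
    which Pearson correlations are computed on demand, or by a precomputed
    long-format correlation table.  Pairs absent from a precomputed table are
    treated as r = 0 (a warning is emitted once per panel).
    """

    def __init__(
        self,
        dosages: pd.DataFrame | None = None,
        correlations: pd.DataFrame | None = None,
        snp_info: pd.DataFrame | None = None,
    ):
        if (dosages is None) == (correlations is None):
            raise ValueError("provide exactly one of dosages or correlations")
        self.dosages = dosages
        self.snp_info = snp_info
        self._warned_missing = False
        if dosages is not None:
            self.rsids = list(dosages.columns)
            self._corr_cache: dict[tuple[str, str], float] = {}
            self._corr_table = None
        else:
            need = {"rsid_a", "rsid_b", "r"}
            if not need.issubset(correlations.columns):
                raise SchemaError(f"correlation table needs columns {sorted(need)}")
            bad = correlations[(correlations["r"] < -1) | (correlations["r"] > 1)]
            if len(bad):
                raise ValueError("correlations outside [-1, 1]")
            table: dict[tuple[str, str], float] = {}
            ids: set[str] = set()
            for a, b, r in correlations[["rsid_a", "rsid_b", "r"]].itertuples(index=False):
                a, b = str(a), str(b)
                table[(a, b)] = float(r)
                table[(b, a)] = float(r)
                ids.update((a, b))
            self._corr_table = table
            self.rsids = sorted(ids)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame, snp_info: pd.DataFrame | None = None) -> "LdPanel":
        return cls(dosages=dosages, snp_info=snp_info)

    @classmethod
    def from_correlations(cls, correlations: pd.DataFrame) -> "LdPanel":
        return cls(correlations=correlations)

    # -- queries ------------------------------------------------------------
    def r(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self._corr_table is not None:
            val = self._corr_table.get((a, b))
            if val is None:
                self._warn_missing(a, b)
                return 0.0
            return val
        key = (a, b) if a <= b else (b, a)
        if key in self._corr_cache:
            return self._corr_cache[key]
        if a not in self.dosages.columns or b not in self.dosages.columns:
            self._warn_missing(a, b)
            return 0.0
        x = self.dosages[a].to_numpy(dtype=float)
        y = self.dosages[b].to_numpy(dtype=float)
        sx, sy = x.std(), y.std()
        val = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x, y)[0, 1])
        self._corr_cache[key] = val
        return val

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def corr_matrix(self, rsids) -> np.ndarray:
        """Correlation matrix for a list of SNPs (missing pairs -> 0)."""
        rsids = list(rsids)
        if self.dosages is not None and all(s in self.dosages.columns for s in rsids):
            mat = self.dosages[rsids].to_numpy(dtype=float)
            sd = mat.std(axis=0)
            if np.all(sd > 0):
                out = np.corrcoef(mat, rowvar=False)
                return np.atleast_2d(out)
        m = len(rsids)
        out = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                out[i, j] = out[j, i] = self.r(rsids[i], rsids[j])
        return out

    def _warn_missing(self, a: str, b: str) -> None:
        if not self._warned_missing:
            warnings.warn(
                f"LD panel does not cover pair ({a}, {b}); treating missing pairs as r=0",
                stacklevel=3,
            )
            self._warned_missing = True


def read_ld_panel(path, kind: str = "dosage", sep: str = "\t") -> LdPanel:
    """Read an LD panel from a dosage matrix TSV or a 3-column correlation TSV."""
    df = pd.read_csv(path, sep=sep)
    if kind == "dosage":
        return LdPanel.from_dosages(df)
    if kind == "correlations":
        return LdPanel.from_correlations(df)
    raise ValueError(f"kind must be 'dosage' or 'correlations', got {kind!r}")


def write_ld_dosages(panel: LdPanel, path, sep: str = "\t") -> None:
    if panel.dosages is None:
        raise ValueError("panel has no dosage matrix")
    panel.dosages.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------


def write_results(tables: dict, out_dir, sep: str = "\t") -> dict:
    """Write a mapping of name -> DataFrame as ``<out_dir>/<name>.tsv``.

    Floats are printed with 12 significant digits so that a write/read round
    trip preserves values to the documented precision.  Returns the mapping
    of name -> written path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep=sep, index=False, float_format="%.12g")
        paths[name] = path
    return paths
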