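"""Readers and writers for the package's on-disk formats.

TSV dialect: UTF-8, tab-separated, mandatory header row, ``#``-prefixed
comment lines permitted anywhere.  Loci are identified by id and their
file order is authoritative (contiguous within chromosome); VCF positions
are 1-based per the standard, internal indices 0-based.

Formats:

* genotypes  — ``locus  chrom  <ind>_h1  <ind>_h2 ...``, one row per locus,
  alleles 0/1; or a phased VCF (``0|1``-style GT; unphased records are an
  error).
* effects    — ``locus  <trait1>  <trait2> ...``, real-valued.
* recomb map — ``locus_left  locus_right  r``.
* values     — ``individual  <trait1> ...``.
* evaluation — values columns plus optional ``w_<trait>`` provenance
  weight columns.
* run record — JSON capturing command, configuration, seeds, input
  digests, package version and the outputs manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breeding import RecombinationMap
from .core import EffectMatrix, GeneticValues, GenotypeMatrix
from .errors import AlignmentError, FormatError
from .metrics import EvaluationSet

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_effects", "write_effects",
    "read_recomb_map", "write_recomb_map",
    "read_values", "write_values",
    "read_evaluation_set", "write_evaluation_set",
    "RunRecord", "write_run_record",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.columns.size and df.columns[0].startswith("Unnamed"):
        raise FormatError(f"{path}: missing header row")
    return df


def _numeric(df: pd.DataFrame, cols, path) -> np.ndarray:
    sub = df[cols]
    try:
        return sub.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in columns {list(cols)} ({exc})") from exc


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotypes(path, G: GenotypeMatrix) -> None:
    cols = {"locus": G.locus_ids, "chrom": G.chromosome_of_locus}
    for i, ind in enumerate(G.individual_ids):
        cols[f"{ind}_h1"] = G.haplotypes[i, 0]
        cols[f"{ind}_h2"] = G.haplotypes[i, 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["locus", "chrom"]:
        raise FormatError(f"{path}: genotype header must start with 'locus\\tchrom'")
    hap_cols = list(df.columns[2:])
    if len(hap_cols) % 2:
        raise FormatError(f"{path}: haplotype columns must come in _h1/_h2 pairs")
    individuals = []
    for a, b in zip(hap_cols[::2], hap_cols[1::2]):
        if not (a.endswith("_h1") and b.endswith("_h2") and a[:-3] == b[:-3]):
            raise FormatError(f"{path}: columns {a!r}/{b!r} are not a _h1/_h2 pair")
        individuals.append(a[:-3])
    loci = df["locus"].tolist()
    if len(set(loci)) != len(loci):
        dup = next(x for x in loci if loci.count(x) > 1)
        raise FormatError(f"{path}: duplicated locus id {dup!r}")
    chrom = _numeric(df, ["chrom"], path).astype(np.int64).ravel()
    alleles = _numeric(df, hap_cols, path)
    if not np.isin(alleles, [0.0, 1.0]).all():
        raise FormatError(f"{path}: alleles must be 0 or 1")
    L, n = len(loci), len(individuals)
    haps = np.empty((n, 2, L), dtype=np.int8)
    haps[:, 0, :] = alleles[:, 0::2].T
    haps[:, 1, :] = alleles[:, 1::2].T
    return GenotypeMatrix(individuals, loci, chrom, haps)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    loci: list[str] = []
    chrom_labels: list[int] = []
    contig_order: dict[str, int] = {}
    rows = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(
                f"{path}: non-biallelic record at {rec.chrom}:{rec.pos}"
            )
        if rec.chrom not in contig_order:
            contig_order[rec.chrom] = len(contig_order) + 1
        locus = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        if locus in loci:
            raise FormatError(f"{path}: duplicated locus id {locus!r}")
        row = np.empty((len(samples), 2), dtype=np.int8)
        for s_idx, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                raise FormatError(
                    f"{path}: missing diploid GT at {rec.chrom}:{rec.pos} sample {s}"
                )
            if not call.phased:
                raise FormatError(
                    f"{path}: unphased GT at {rec.chrom}:{rec.pos} sample {s}"
                )
            if any(a not in (0, 1) for a in gt):
                raise FormatError(
                    f"{path}: allele index out of range at {rec.chrom}:{rec.pos}"
                )
            row[s_idx] = gt
        loci.append(locus)
        chrom_labels.append(contig_order[rec.chrom])
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: VCF contains no records")
    haps = np.stack(rows, axis=-1)  # (n_samples, 2, L)
    return GenotypeMatrix(samples, loci, np.array(chrom_labels), haps)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from TSV or phased VCF (auto-detected by suffix)."""
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# effects / recombination map / values
# ---------------------------------------------------------------------------


def write_effects(path, B: EffectMatrix) -> None:
    df = pd.DataFrame(B.effects, columns=B.trait_ids)
    df.insert(0, "locus", B.locus_ids)
    df.to_csv(path, sep="\t", index=False)


def read_effects(path, genotypes: GenotypeMatrix | None = None) -> EffectMatrix:
    df = _read_tsv(path)
    if df.columns[0] != "locus" or df.columns.size < 2:
        raise FormatError(f"{path}: effects header must be 'locus\\t<trait>...'")
    loci = df["locus"].tolist()
    traits = list(df.columns[1:])
    eff = _numeric(df, traits, path)
    B = EffectMatrix(loci, traits, eff)
    if genotypes is not None and genotypes.locus_ids != loci:
        missing = set(loci) ^ set(genotypes.locus_ids)
        raise AlignmentError(
            f"{path}: effect loci do not align with genotypes "
            f"(symmetric difference {sorted(missing)[:5]}...)"
        )
    return B


def write_recomb_map(path, rmap: RecombinationMap) -> None:
    df = pd.DataFrame({
        "locus_left": rmap.locus_ids[:-1],
        "locus_right": rmap.locus_ids[1:],
        "r": rmap.r,
    })
    df.to_csv(path, sep="\t", index=False)


def read_recomb_map(path, genotypes: GenotypeMatrix) -> RecombinationMap:
    """Recombination map; the genotype matrix supplies locus order and
    chromosome assignment and is checked interval-by-interval."""
    df = _read_tsv(path)
    need = ["locus_left", "locus_right", "r"]
    if list(df.columns[:3]) != need:
        header = "\\t".join(need)
        raise FormatError(f"{path}: recomb header must be {header}")
    left = df["locus_left"].tolist()
    right = df["locus_right"].tolist()
    r = _numeric(df, ["r"], path).ravel()
    exp_left = genotypes.locus_ids[:-1]
    exp_right = genotypes.locus_ids[1:]
    if left != exp_left or right != exp_right:
        raise FormatError(
            f"{path}: intervals are misordered or do not match the genotype loci"
        )
    return RecombinationMap(genotypes.locus_ids, r, genotypes.chromosome_of_locus)


def write_values(path, V: GeneticValues) -> None:
    df = pd.DataFrame(V.values, columns=V.trait_ids)
    df.insert(0, "individual", V.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def read_values(path, is_normalized: bool = False) -> GeneticValues:
    df = _read_tsv(path)
    if df.columns[0] != "individual" or df.columns.size < 2:
        raise FormatError(f"{path}: values header must be 'individual\\t<trait>...'")
    traits = list(df.columns[1:])
    vals = _numeric(df, traits, path)
    return GeneticValues(df["individual"].tolist(), traits, vals, is_normalized)


# ---------------------------------------------------------------------------
# evaluation sets (metrics input/output)
# ---------------------------------------------------------------------------


def write_evaluation_set(path, es: EvaluationSet, trait_ids=None) -> None:
    K = es.n_traits
    traits = list(trait_ids) if trait_ids else [f"trait{k + 1}" for k in range(K)]
    df = pd.DataFrame(es.values, columns=traits)
    df.insert(0, "individual",
              [ind.id or f"{es.label}_{i}" for i, ind in enumerate(es.individuals)])
    has_w = all(ind.provenance_weights is not None for ind in es.individuals)
    if has_w:
        W = np.vstack([ind.provenance_weights for ind in es.individuals])
        for k, t in enumerate(traits):
            df[f"w_{t}"] = W[:, k]
    df.to_csv(path, sep="\t", index=False)


def read_evaluation_set(path, label: str = "") -> EvaluationSet:
    df = _read_tsv(path)
    if df.columns[0] != "individual":
        raise FormatError(f"{path}: evaluation header must start with 'individual'")
    trait_cols = [c for c in df.columns[1:] if not c.startswith("w_")]
    w_cols = [f"w_{c}" for c in trait_cols]
    have_w = all(c in df.columns for c in w_cols)
    values = _numeric(df, trait_cols, path)
    weights = _numeric(df, w_cols, path) if have_w else None
    return EvaluationSet.from_arrays(values, weights, label=label or str(path),
                                     ids=df["individual"].tolist())


# ---------------------------------------------------------------------------
# run records
# ---------------------------------------------------------------------------


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunRecord:
    """Provenance sufficient to re-execute a run bit-identically."""

    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = __version__
    outputs: list = field(default_factory=list)

    @classmethod
    def capture(cls, command: str, config: dict, seeds: dict | None = None,
                inputs: list | None = None, outputs: list | None = None) -> "RunRecord":
        digests = {str(p): _digest(p) for p in (inputs or []) if Path(p).exists()}
        return cls(command, config, seeds or {}, digests,
                   __version__, [str(o) for o in (outputs or [])])


def write_run_record(path, record: RunRecord) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(record), fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
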