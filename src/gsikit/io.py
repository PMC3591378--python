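"""Readers and writers for genotype tables and baseline allele counts.

Two on-disk formats are supported for genotypes:

* the native CSV dialect, with header
  ``individual_id,population,year,site,length_mm,mass_g,<locus1>,...``,
  diploid calls written ``X/Y``, composite calls as a single token and
  missing calls as ``-``;
* GenePop files (diploid loci only), where alleles are 2- or 3-digit
  codes and ``00``/``000`` marks a missing allele.

Baseline allele counts travel as a long-format CSV with columns
``population,stock_group,locus,allele,count``.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .loci import (
    DIPLOID,
    MISSING,
    BaselineSet,
    GenotypeRecord,
    LocusDefinition,
    canonical_diploid_call,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_genepop",
    "read_baseline_counts",
    "write_baseline_counts",
    "ParseError",
]

MISSING_TOKEN = "-"
_META_COLUMNS = ["individual_id", "population", "year", "site", "length_mm", "mass_g"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def _parse_call(token: str, locus: LocusDefinition, row: str):
    token = token.strip()
    if token == MISSING_TOKEN or token == "":
        return MISSING
    if locus.is_diploid:
        parts = token.split("/")
        if len(parts) != 2:
            raise ParseError(
                f"row {row!r}, locus {locus.name}: expected 'X/Y' call, got {token!r}"
            )
        call = canonical_diploid_call(parts[0], parts[1])
    else:
        call = token
    try:
        locus.validate_call(call)
    except ValueError as exc:
        raise ParseError(f"row {row!r}, locus {locus.name}: {exc}") from exc
    return call


def _format_call(call, locus: LocusDefinition) -> str:
    if call is MISSING:
        return MISSING_TOKEN
    return "/".join(call) if locus.is_diploid else str(call)


def read_genotypes(path, locus_defs: Sequence[LocusDefinition]):
    """Read the native genotype CSV into a list of :class:`GenotypeRecord`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "individual_id":
        raise ParseError(
            f"malformed header: first column must be 'individual_id', "
            f"got {df.columns[0]!r}"
        )
    by_name = {loc.name: loc for loc in locus_defs}
    locus_cols = [c for c in df.columns if c not in _META_COLUMNS]
    unknown = [c for c in locus_cols if c not in by_name]
    if unknown:
        raise ParseError(f"unknown loci in header: {unknown}")

    records = []
    for _, row in df.iterrows():
        rid = row["individual_id"]
        calls = {
            name: _parse_call(row[name], by_name[name], rid) for name in locus_cols
        }

        def _opt(col, conv):
            val = row.get(col, "")
            return conv(val) if val not in ("", None) else None

        records.append(
            GenotypeRecord(
                individual_id=rid,
                calls=calls,
                length_mm=_opt("length_mm", float),
                mass_g=_opt("mass_g", float),
                capture_site=_opt("site", str),
                year=_opt("year", int),
                population=_opt("population", str),
            )
        )
    return records


def write_genotypes(path, records, locus_defs: Sequence[LocusDefinition]) -> None:
    """Write records in the native CSV dialect (inverse of :func:`read_genotypes`)."""
    rows = []
    for rec in records:
        row = {
            "individual_id": rec.individual_id,
            "population": rec.population if rec.population is not None else "",
            "year": rec.year if rec.year is not None else "",
            "site": rec.capture_site if rec.capture_site is not None else "",
            "length_mm": rec.length_mm if rec.length_mm is not None else "",
            "mass_g": rec.mass_g if rec.mass_g is not None else "",
        }
        for loc in locus_defs:
            row[loc.name] = _format_call(rec.calls.get(loc.name, MISSING), loc)
        rows.append(row)
    cols = _META_COLUMNS + [loc.name for loc in locus_defs]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_genepop(path):
    """Read a GenePop file (diploid loci only).

    Returns ``(records, locus_defs)`` where allele symbols are the numeric
    codes stripped of leading zeros ("01" -> "1").  Population membership is
    recorded as ``pop_1``, ``pop_2``, ... in file order.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError("empty GenePop file")
    body = lines[1:]  # first line is the title
    locus_names = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if i == len(body):
        raise ParseError("GenePop file has no 'Pop' separator")

    raw = []  # (pop index, individual id, [(a1, a2) or None])
    pop_idx = 1
    for ln in body[i + 1:]:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in stripped:
            raise ParseError(f"GenePop line without ',' separator: {stripped!r}")
        ident, _, geno = stripped.partition(",")
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"individual {ident.strip()!r}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci"
            )
        calls = []
        for name, tok in zip(locus_names, tokens):
            if not re.fullmatch(r"\d{4}|\d{6}", tok):
                raise ParseError(
                    f"individual {ident.strip()!r}, locus {name}: bad code {tok!r}"
                )
            w = len(tok) // 2
            a1, a2 = tok[:w], tok[w:]
            if int(a1) == 0 or int(a2) == 0:
                calls.append(None)
            else:
                calls.append((str(int(a1)), str(int(a2))))
        raw.append((pop_idx, ident.strip(), calls))

    alleles = {name: set() for name in locus_names}
    for _, _, calls in raw:
        for name, call in zip(locus_names, calls):
            if call is not None:
                alleles[name].update(call)
    locus_defs = [
        LocusDefinition(name, DIPLOID, tuple(sorted(alleles[name], key=int)))
        for name in locus_names
        if alleles[name]
    ]
    kept = {loc.name for loc in locus_defs}

    records = []
    for pop, ident, calls in raw:
        call_map = {}
        for name, call in zip(locus_names, calls):
            if name not in kept:
                continue
            call_map[name] = (
                MISSING if call is None else canonical_diploid_call(*call)
            )
        records.append(
            GenotypeRecord(
                individual_id=ident, calls=call_map, population=f"pop_{pop}"
            )
        )
    return records, locus_defs


def read_baseline_counts(
    path,
    locus_defs: Sequence[LocusDefinition],
    groups: Optional[Sequence[str]] = None,
) -> BaselineSet:
    """Read a long-format ``population,stock_group,locus,allele,count`` CSV."""
    df = pd.read_csv(path, dtype={"population": str, "stock_group": str,
                                  "locus": str, "allele": str, "count": np.int64})
    expected = {"population", "stock_group", "locus", "allele", "count"}
    if not expected.issubset(df.columns):
        raise ParseError(f"baseline counts header must contain {sorted(expected)}")
    by_name = {loc.name: loc for loc in locus_defs}
    unknown = sorted(set(df["locus"]) - set(by_name))
    if unknown:
        raise ParseError(f"unknown loci in baseline counts: {unknown}")

    pops = list(dict.fromkeys(df["population"]))
    group_map = {}
    for pop, grp in zip(df["population"], df["stock_group"]):
        if group_map.setdefault(pop, grp) != grp:
            raise ParseError(f"population {pop!r} mapped to multiple stock groups")
    if groups is None:
        groups = tuple(dict.fromkeys(df["stock_group"]))
    counts = {
        pop: {n: np.zeros(len(loc.alleles), dtype=np.int64)
              for n, loc in by_name.items()}
        for pop in pops
    }
    for _, row in df.iterrows():
        loc = by_name[row["locus"]]
        idx = loc.allele_index()
        if row["allele"] not in idx:
            raise ParseError(
                f"population {row['population']}, locus {row['locus']}: "
                f"allele {row['allele']!r} outside alphabet"
            )
        counts[row["population"]][row["locus"]][idx[row["allele"]]] += row["count"]
    return BaselineSet(
        loci=list(locus_defs),
        populations=pops,
        group_map=group_map,
        groups=tuple(groups),
        counts=counts,
    )


def write_baseline_counts(path, baseline: BaselineSet) -> None:
    rows = []
    for pop in baseline.populations:
        for loc in baseline.loci:
            for allele, count in zip(loc.alleles, baseline.counts[pop][loc.name]):
                rows.append(
                    {
                        "population": pop,
                        "stock_group": baseline.group_map[pop],
                        "locus": loc.name,
                        "allele": allele,
                        "count": int(count),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
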