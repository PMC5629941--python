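"""Classical HLA alleles, amino-acid residue content, and dosage markers.

The MHC analysis operates on four marker categories: biallelic SNPs,
amino-acid residue indicators, and classical HLA alleles at two- and
four-digit resolution.  A :class:`ResidueMap` records which residue each
classical allele carries at each polymorphic position of the mature protein;
:func:`expand_alleles_to_markers` turns allele dosages into residue-indicator
dosages (the dosage of residue ``x`` at position ``p`` is the summed dosage
of the alleles carrying ``x`` at ``p``), and :func:`group_markers` collects
markers into the testable units of the omnibus test: one group per SNP, one
multiallelic group per amino-acid position, one per HLA locus/resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP = "SNP"
AA_RESIDUE = "AA_RESIDUE"
HLA_2DIGIT = "HLA_2DIGIT"
HLA_4DIGIT = "HLA_4DIGIT"
MARKER_KINDS = (SNP, AA_RESIDUE, HLA_2DIGIT, HLA_4DIGIT)

_ALLELE_RE = re.compile(r"^([A-Z][A-Z0-9]*)\*(\d{2})(?::(\d{2}))?$")


def parse_allele(name: str) -> tuple[str, str, str | None]:
    """Split ``GENE*DD[:DD]`` into (gene, 2-digit family, 4-digit subtype)."""
    m = _ALLELE_RE.match(name)
    if m is None:
        raise ValueError(
            f"allele name {name!r} does not follow GENE*DD or GENE*DD:DD syntax"
        )
    return m.group(1), m.group(2), m.group(3)


@dataclass(frozen=True)
class Marker:
    """One dosage column: a SNP, a residue indicator, or a classical allele."""

    marker_id: str
    kind: str
    group_id: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")


@dataclass(frozen=True)
class MarkerGroup:
    """A testable unit: the member markers entering one omnibus test."""

    group_id: str
    kind: str
    members: tuple[Marker, ...]

    @property
    def size(self) -> int:
        return len(self.members)


class ResidueMap:
    """Lookup from classical HLA allele to amino-acid residue per position.

    Parameters
    ----------
    entries
        DataFrame with columns ``allele``, ``gene``, ``position``,
        ``residue`` — one row per (allele, position) with the single-letter
        residue code the allele carries there.
    """

    COLUMNS = ("allele", "gene", "position", "residue")

    def __init__(self, entries: pd.DataFrame) -> None:
        entries = entries.loc[:, list(self.COLUMNS)].copy()
        entries["position"] = entries["position"].astype(int)
        for allele in entries["allele"].unique():
            parse_allele(allele)
        if (entries["position"] < 1).any():
            raise ValueError("positions must be >= 1")
        dup = entries.duplicated(subset=["allele", "gene", "position"])
        if dup.any():
            bad = entries.loc[dup, ["allele", "position"]].iloc[0]
            raise ValueError(
                f"duplicate residue-map entry for {bad['allele']} "
                f"position {bad['position']}"
            )
        self.entries = entries.reset_index(drop=True)
        self._lookup = {
            (r.allele, r.gene, r.position): r.residue
            for r in entries.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())

    def positions(self, gene: str) -> list[int]:
        sub = self.entries[self.entries["gene"] == gene]
        return sorted(sub["position"].unique())

    def residues_at(self, gene: str, position: int) -> list[str]:
        sub = self.entries[
            (self.entries["gene"] == gene) & (self.entries["position"] == position)
        ]
        return sorted(sub["residue"].unique())

    def residue(self, allele: str, gene: str, position: int) -> str:
        try:
            return self._lookup[(allele, gene, position)]
        except KeyError:
            raise KeyError(
                f"allele {allele} has no residue entry for {gene} position {position}"
            ) from None

    @classmethod
    def from_tsv(cls, path) -> "ResidueMap":
        df = pd.read_csv(path, sep="\t", dtype={"allele": str, "gene": str,
                                                "residue": str})
        return cls(df)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


@dataclass
class DosageMatrix:
    """Samples x markers dosage matrix with per-marker imputation info scores.

    Dosages are expected allele counts in [0, 2]; missing values are NaN.
    """

    markers: list[Marker]
    samples: list[str]
    dosage: np.ndarray  # (n_samples, n_markers), float, NaN = missing
    info: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.info is None:
            self.info = np.ones(len(self.markers))
        self.info = np.asarray(self.info, dtype=float)
        if self.info.shape != (len(self.markers),):
            raise ValueError("info must have one entry per marker")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0.0) < -1e-9 or (
                np.nanmax(self.dosage, initial=0.0) > 2 + 1e-9
            ):
                raise ValueError("dosages must lie in [0, 2]")
        if ((self.info < -1e-9) | (self.info > 1 + 1e-9)).any():
            raise ValueError("info scores must lie in [0, 1]")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")
        self._index = {mid: j for j, mid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def column(self, marker_id: str) -> np.ndarray:
        return self.dosage[:, self._index[marker_id]]

    def marker(self, marker_id: str) -> Marker:
        return self.markers[self._index[marker_id]]

    def select_markers(self, marker_ids) -> "DosageMatrix":
        idx = [self._index[m] for m in marker_ids]
        return DosageMatrix(
            markers=[self.markers[j] for j in idx],
            samples=list(self.samples),
            dosage=self.dosage[:, idx].copy(),
            info=self.info[idx].copy(),
        )

    def select_samples(self, sample_ids) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return DosageMatrix(
            markers=list(self.markers),
            samples=list(sample_ids),
            dosage=self.dosage[idx, :].copy(),
            info=self.info.copy(),
        )

    def of_kind(self, kind: str) -> "DosageMatrix":
        return self.select_markers(
            [m.marker_id for m in self.markers if m.kind == kind]
        )

    def concat_markers(self, other: "DosageMatrix") -> "DosageMatrix":
        if self.samples != other.samples:
            raise ValueError("sample lists differ")
        return DosageMatrix(
            markers=self.markers + other.markers,
            samples=list(self.samples),
            dosage=np.hstack([self.dosage, other.dosage]),
            info=np.concatenate([self.info, other.info]),
        )

    def allele_frequencies(self, sample_ids=None) -> pd.Series:
        """Frequency of the dosage-counted label, mean(dosage)/2, per marker.

        Missing dosages are excluded from the mean.
        """
        if sample_ids is None:
            d = self.dosage
        else:
            pos = {s: i for i, s in enumerate(self.samples)}
            d = self.dosage[[pos[s] for s in sample_ids], :]
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(d, axis=0) / 2.0
        return pd.Series(freq, index=self.marker_ids)

    # ------------------------------------------------------------------ IO
    def to_tsv(self, path) -> None:
        """Write the marker-major TSV format.

        Row 1: ``marker_id kind group_id label info <sample ids...>``;
        one row per marker, missing dosage encoded ``NA``.
        """
        df = pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "kind": [m.kind for m in self.markers],
                "group_id": [m.group_id for m in self.markers],
                "label": [m.label for m in self.markers],
                "info": self.info,
            }
        )
        dos = pd.DataFrame(self.dosage.T, columns=self.samples)
        pd.concat([df, dos], axis=1).to_csv(
            path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
        )

    @classmethod
    def from_tsv(cls, path) -> "DosageMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"],
                         dtype={"marker_id": str, "label": str})
        meta_cols = ["marker_id", "kind", "group_id", "label", "info"]
        samples = [c for c in df.columns if c not in meta_cols]
        markers = [
            Marker(r.marker_id, r.kind, r.group_id, str(r.label))
            for r in df[meta_cols].itertuples(index=False)
        ]
        dosage = df[samples].to_numpy(dtype=float).T
        return cls(markers=markers, samples=samples, dosage=dosage,
                   info=df["info"].to_numpy(dtype=float))

    @classmethod
    def from_vcf(cls, path, dosage_field: str = "DS") -> "DosageMatrix":
        """Read biallelic SNP records with a per-genotype dosage FORMAT field.

        Each record becomes one SNP marker (group of size one); the dosage
        counts the ALT allele.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        markers, rows = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            mid = var.ID or f"{var.CHROM}_{var.POS}_{var.REF}_{var.ALT[0]}"
            markers.append(Marker(mid, SNP, mid, var.ALT[0]))
            ds = np.asarray(var.format(dosage_field), dtype=float).reshape(-1)
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
            rows.append(ds)
        dosage = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
        return cls(markers=markers, samples=samples, dosage=dosage)


def expand_alleles_to_markers(
    allele_dosages: DosageMatrix, residue_map: ResidueMap
) -> DosageMatrix:
    """Expand 4-digit classical allele dosages into residue-indicator dosages.

    For every gene and mapped position, the dosage of residue ``x`` is the sum
    of the dosages of the gene's alleles carrying ``x`` there, so per-sample
    residue dosages at a position conserve the summed allele dosage.  A
    missing allele dosage makes every residue dosage of that gene missing for
    that sample (the residue content of the missing haplotypes is unknown).

    Raises
    ------
    KeyError
        If an allele with nonzero dosage lacks a map entry at a mapped
        position of its gene.
    """
    alleles = [m for m in allele_dosages.markers if m.kind == HLA_4DIGIT]
    by_gene: dict[str, list[Marker]] = {}
    for m in alleles:
        gene, _, _ = parse_allele(m.marker_id)
        by_gene.setdefault(gene, []).append(m)

    out_markers: list[Marker] = []
    out_cols: list[np.ndarray] = []
    n = allele_dosages.n_samples
    for gene in residue_map.genes():
        gene_alleles = by_gene.get(gene, [])
        if not gene_alleles:
            continue
        cols = np.column_stack(
            [allele_dosages.column(m.marker_id) for m in gene_alleles]
        )
        missing_any = np.isnan(cols).any(axis=1)
        for pos in residue_map.positions(gene):
            residues: dict[str, np.ndarray] = {}
            for j, m in enumerate(gene_alleles):
                carried = (~np.isnan(cols[:, j])) & (cols[:, j] > 0)
                try:
                    res = residue_map.residue(m.marker_id, gene, pos)
                except KeyError:
                    if carried.any():
                        raise KeyError(
                            f"allele {m.marker_id} (nonzero dosage) absent from "
                            f"residue map at {gene} position {pos}"
                        ) from None
                    continue
                acc = residues.setdefault(res, np.zeros(n))
                acc += np.nan_to_num(cols[:, j])
            group = f"{gene}_{pos}"
            for res in sorted(residues):
                col = residues[res].copy()
                col[missing_any] = np.nan
                out_markers.append(
                    Marker(f"AA_{group}_{res}", AA_RESIDUE, group, res)
                )
                out_cols.append(np.clip(col, 0.0, 2.0))
    dosage = (
        np.column_stack(out_cols) if out_cols else np.empty((n, 0))
    )
    return DosageMatrix(
        markers=out_markers, samples=list(allele_dosages.samples), dosage=dosage
    )


def collapse_to_2digit(allele_dosages: DosageMatrix) -> DosageMatrix:
    """Sum 4-digit allele dosages over subtypes to 2-digit family dosages."""
    alleles = [m for m in allele_dosages.markers if m.kind == HLA_4DIGIT]
    fam_cols: dict[tuple[str, str], np.ndarray] = {}
    fam_missing: dict[tuple[str, str], np.ndarray] = {}
    n = allele_dosages.n_samples
    for m in alleles:
        gene, family, _ = parse_allele(m.marker_id)
        key = (gene, family)
        col = allele_dosages.column(m.marker_id)
        fam_cols.setdefault(key, np.zeros(n))
        fam_missing.setdefault(key, np.zeros(n, dtype=bool))
        fam_cols[key] += np.nan_to_num(col)
        fam_missing[key] |= np.isnan(col)
    markers, cols = [], []
    for (gene, family) in sorted(fam_cols):
        name = f"{gene}*{family}"
        col = np.clip(fam_cols[(gene, family)], 0.0, 2.0)
        col[fam_missing[(gene, family)]] = np.nan
        markers.append(Marker(name, HLA_2DIGIT, f"{gene}_2digit", name))
        cols.append(col)
    dosage = np.column_stack(cols) if cols else np.empty((n, 0))
    return DosageMatrix(markers=markers, samples=list(allele_dosages.samples),
                        dosage=dosage)


def hla_allele_markers(allele_names, kind: str = HLA_4DIGIT) -> list[Marker]:
    """Build Marker records for classical alleles, grouped per locus/resolution."""
    suffix = "4digit" if kind == HLA_4DIGIT else "2digit"
    markers = []
    for name in allele_names:
        gene, _, subtype = parse_allele(name)
        if kind == HLA_4DIGIT and subtype is None:
            raise ValueError(f"{name} is not a 4-digit allele")
        markers.append(Marker(name, kind, f"{gene}_{suffix}", name))
    return markers


def group_markers(
    markers, control_frequencies: pd.Series | dict | None = None
) -> list[MarkerGroup]:
    """Collect markers into testable groups.

    SNPs form singleton groups; residue indicators group per (gene, position);
    classical alleles group per locus and resolution.  Within a group, members
    are ordered by control frequency descending (when supplied; ties and the
    no-frequency case fall back to marker id), so the first member of a
    multiallelic group is the omnibus reference candidate.
    """
    if control_frequencies is None:
        freq = {}
    elif isinstance(control_frequencies, pd.Series):
        freq = control_frequencies.to_dict()
    else:
        freq = dict(control_frequencies)
    by_group: dict[str, list[Marker]] = {}
    order: list[str] = []
    for m in markers:
        if m.group_id not in by_group:
            order.append(m.group_id)
        by_group.setdefault(m.group_id, []).append(m)
    groups = []
    for gid in order:
        members = sorted(
            by_group[gid],
            key=lambda m: (-freq.get(m.marker_id, 0.0), m.marker_id),
        )
        kinds = {m.kind for m in members}
        if len(kinds) != 1:
            raise ValueError(f"group {gid} mixes marker kinds {sorted(kinds)}")
        groups.append(MarkerGroup(gid, members[0].kind, tuple(members)))
    return groups
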