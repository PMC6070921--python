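"""Panel definition for targeted AR profiling.

A :class:`PanelConfig` bundles everything the downstream stages need to know
about the assay: the locus sequence (an AR-like gene transcribed on the plus
strand), its exon catalog (canonical exons E1..E8 plus cryptic exons CE*),
the named splice-junction catalog (AR-FL and the AR-V isoforms), capture
target intervals for the DNA assay, control-gene loci used for coverage
normalisation, the RNA panel genes (five androgen-responsive genes and three
housekeeping genes), and the hotspot mutation table.

Coordinates are 0-based, half-open throughout.  The real AR gene lies on the
minus strand of X; the pipeline operates in transcript orientation after
configuration, so strand is only a config attribute applied at import/export
time.  Configs are stored as a single YAML document so that mock loci and a
real panel travel through exactly the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

VALID_BASES = set("ACGT")


class PanelConfigError(ValueError):
    """Raised when a panel configuration violates a structural invariant."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise PanelConfigError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Exon:
    """An exon of the panel locus, with its sequence materialised."""

    id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise PanelConfigError(
                f"exon {self.id}: interval length {self.end - self.start} "
                f"!= sequence length {len(self.sequence)}"
            )
        if len(self.sequence) == 0:
            raise PanelConfigError(f"exon {self.id} is empty")


@dataclass(frozen=True)
class JunctionDef:
    """A named splice junction joining the 3' end of one exon to the 5'
    start of another (e.g. AR-V7 = E3 -> CE3)."""

    variant_name: str
    upstream: str
    downstream: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.upstream, self.downstream)

    def label(self) -> str:
        return f"{self.upstream}->{self.downstream}"


@dataclass(frozen=True)
class HotspotDef:
    """A recurrent point mutation at a fixed locus position (e.g. T878A)."""

    name: str
    chrom: str
    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class RnaGene:
    """An RNA panel gene with its role in signalling-score computation."""

    id: str
    role: str  # "ar_regulated" | "housekeeping"


@dataclass
class PanelConfig:
    locus_name: str
    locus_sequence: str
    exons: list[Exon]
    junctions: list[JunctionDef]
    dna_targets: list[Interval]
    control_targets: list[Interval]
    rna_genes: list[RnaGene]
    hotspots: list[HotspotDef]
    control_loci: dict[str, str] = field(default_factory=dict)
    strand: str = "+"
    canonical_name: str = "AR-FL"
    locus_ploidy: int = 1  # X-linked gene in a male genome
    control_ploidy: int = 2  # autosomal control genes

    # -- lookups ---------------------------------------------------------

    def exon_by_id(self, exon_id: str) -> Exon:
        for exon in self.exons:
            if exon.id == exon_id:
                return exon
        raise PanelConfigError(f"unknown exon {exon_id!r}")

    def sequences(self) -> dict[str, str]:
        """All reference sequences keyed by name (locus plus controls)."""
        seqs = {self.locus_name: self.locus_sequence}
        seqs.update(self.control_loci)
        return seqs

    def canonical_junctions(self) -> list[JunctionDef]:
        return [j for j in self.junctions if j.variant_name == self.canonical_name]

    def variant_junctions(self) -> list[JunctionDef]:
        return [j for j in self.junctions if j.variant_name != self.canonical_name]

    def junction_for_variant(self, variant_name: str) -> JunctionDef:
        for j in self.junctions:
            if j.variant_name == variant_name:
                return j
        raise PanelConfigError(f"no junction catalogued for variant {variant_name!r}")

    def housekeeping_genes(self) -> list[str]:
        return [g.id for g in self.rna_genes if g.role == "housekeeping"]

    def ar_regulated_genes(self) -> list[str]:
        return [g.id for g in self.rna_genes if g.role == "ar_regulated"]

    def hotspot_by_name(self, name: str) -> HotspotDef:
        for h in self.hotspots:
            if h.name == name:
                return h
        raise PanelConfigError(f"unknown hotspot {name!r}")

    # -- validation ------------------------------------------------------

    def validate(self) -> "PanelConfig":
        if set(self.locus_sequence) - VALID_BASES:
            raise PanelConfigError("locus sequence contains non-ACGT characters")
        exon_ids = [e.id for e in self.exons]
        if len(set(exon_ids)) != len(exon_ids):
            raise PanelConfigError("duplicate exon ids")
        for exon in self.exons:
            if exon.end > len(self.locus_sequence):
                raise PanelConfigError(f"exon {exon.id} extends beyond locus")
            if self.locus_sequence[exon.start : exon.end] != exon.sequence:
                raise PanelConfigError(
                    f"exon {exon.id} sequence does not match locus at "
                    f"{exon.start}-{exon.end}"
                )
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise PanelConfigError(f"exons {a.id} and {b.id} overlap")

        known = set(exon_ids)
        seen_pairs: set[tuple[str, str]] = set()
        starts = {e.id: e.start for e in self.exons}
        for j in self.junctions:
            for ref in (j.upstream, j.downstream):
                if ref not in known:
                    raise PanelConfigError(
                        f"junction {j.variant_name} ({j.label()}) references "
                        f"unknown exon {ref!r}"
                    )
            if j.key in seen_pairs:
                raise PanelConfigError(f"duplicate junction {j.label()}")
            seen_pairs.add(j.key)
            if starts[j.upstream] >= starts[j.downstream]:
                raise PanelConfigError(
                    f"junction {j.variant_name}: upstream exon {j.upstream} does "
                    f"not precede downstream exon {j.downstream}"
                )

        seqs = self.sequences()
        for iv in self.dna_targets + self.control_targets:
            if iv.chrom not in seqs:
                raise PanelConfigError(f"target on unknown sequence {iv.chrom!r}")
            if iv.end > len(seqs[iv.chrom]):
                raise PanelConfigError(
                    f"target {iv.chrom}:{iv.start}-{iv.end} extends beyond sequence"
                )
        dna_keys = {(iv.chrom, iv.start, iv.end) for iv in self.dna_targets}
        ctrl_keys = {(iv.chrom, iv.start, iv.end) for iv in self.control_targets}
        if dna_keys & ctrl_keys:
            raise PanelConfigError("dna_targets and control_targets overlap")

        for h in self.hotspots:
            if h.chrom not in seqs:
                raise PanelConfigError(f"hotspot {h.name} on unknown sequence")
            if not (0 <= h.position < len(seqs[h.chrom])):
                raise PanelConfigError(f"hotspot {h.name} outside sequence")
            actual = seqs[h.chrom][h.position]
            if actual != h.ref:
                raise PanelConfigError(
                    f"hotspot {h.name}: ref base {h.ref!r} does not match locus "
                    f"base {actual!r} at position {h.position}"
                )
            if h.alt == h.ref or h.alt not in VALID_BASES:
                raise PanelConfigError(f"hotspot {h.name}: invalid alt {h.alt!r}")

        roles = {g.role for g in self.rna_genes}
        if not roles <= {"ar_regulated", "housekeeping"}:
            raise PanelConfigError(f"unknown RNA gene roles: {roles}")
        gene_ids = [g.id for g in self.rna_genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise PanelConfigError("duplicate RNA gene ids")
        return self


# -- grouping --------------------------------------------------------------


def junctions_by_upstream(panel: PanelConfig) -> dict[str, list[JunctionDef]]:
    """Group the junction catalog by upstream exon id.

    The per-variant transcript fraction is defined against the total read
    support of all splice junctions sharing the same upstream exon, so this
    partition drives fraction quantification.
    """
    groups: dict[str, list[JunctionDef]] = {}
    for j in panel.junctions:
        groups.setdefault(j.upstream, []).append(j)
    return groups


# -- (de)serialisation ------------------------------------------------------


def _wrap_seq(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def panel_to_dict(panel: PanelConfig) -> dict:
    return {
        "locus": {
            "name": panel.locus_name,
            "strand": panel.strand,
            "ploidy": panel.locus_ploidy,
            "sequence": panel.locus_sequence,
        },
        "canonical_name": panel.canonical_name,
        "exons": [
            {"id": e.id, "start": e.start, "end": e.end} for e in panel.exons
        ],
        "junctions": [
            {"variant": j.variant_name, "upstream": j.upstream, "downstream": j.downstream}
            for j in panel.junctions
        ],
        "control_loci": [
            {"name": name, "ploidy": panel.control_ploidy, "sequence": seq}
            for name, seq in panel.control_loci.items()
        ],
        "dna_targets": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in panel.dna_targets
        ],
        "control_targets": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in panel.control_targets
        ],
        "rna_genes": [{"id": g.id, "role": g.role} for g in panel.rna_genes],
        "hotspots": [
            {"name": h.name, "chrom": h.chrom, "position": h.position,
             "ref": h.ref, "alt": h.alt}
            for h in panel.hotspots
        ],
    }


def panel_from_dict(doc: dict) -> PanelConfig:
    try:
        locus = doc["locus"]
        locus_seq = "".join(str(locus["sequence"]).split()).upper()
        exons = []
        for e in doc.get("exons", []):
            seq = e.get("sequence")
            if seq is None:
                seq = locus_seq[int(e["start"]) : int(e["end"])]
            exons.append(Exon(str(e["id"]), int(e["start"]), int(e["end"]), seq))
        junctions = [
            JunctionDef(str(j["variant"]), str(j["upstream"]), str(j["downstream"]))
            for j in doc.get("junctions", [])
        ]
        control_loci = {
            str(c["name"]): "".join(str(c["sequence"]).split()).upper()
            for c in doc.get("control_loci", [])
        }
        control_ploidy = 2
        for c in doc.get("control_loci", []):
            control_ploidy = int(c.get("ploidy", 2))
        panel = PanelConfig(
            locus_name=str(locus["name"]),
            locus_sequence=locus_seq,
            exons=exons,
            junctions=junctions,
            dna_targets=[
                Interval(str(t["chrom"]), int(t["start"]), int(t["end"]))
                for t in doc.get("dna_targets", [])
            ],
            control_targets=[
                Interval(str(t["chrom"]), int(t["start"]), int(t["end"]))
                for t in doc.get("control_targets", [])
            ],
            rna_genes=[
                RnaGene(str(g["id"]), str(g["role"]))
                for g in doc.get("rna_genes", [])
            ],
            hotspots=[
                HotspotDef(str(h["name"]), str(h["chrom"]), int(h["position"]),
                           str(h["ref"]).upper(), str(h["alt"]).upper())
                for h in doc.get("hotspots", [])
            ],
            control_loci=control_loci,
            strand=str(locus.get("strand", "+")),
            canonical_name=str(doc.get("canonical_name", "AR-FL")),
            locus_ploidy=int(locus.get("ploidy", 1)),
            control_ploidy=control_ploidy,
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, PanelConfigError):
            raise
        raise PanelConfigError(f"malformed panel config: {exc}") from exc
    return panel.validate()


def load_panel(path: str | Path) -> PanelConfig:
    """Load and validate a panel configuration from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PanelConfigError(f"{path}: not a mapping document")
    return panel_from_dict(doc)


def save_panel(panel: PanelConfig, path: str | Path) -> None:
    """Write a panel configuration to YAML (round-trips field-by-field)."""
    doc = panel_to_dict(panel)
    doc["locus"]["sequence"] = _wrap_seq(doc["locus"]["sequence"])
    for c in doc["control_loci"]:
        c["sequence"] = _wrap_seq(c["sequence"])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


# -- exports ----------------------------------------------------------------


def export_targets_bed(panel: PanelConfig, path: str | Path) -> None:
    """Write DNA and control capture targets as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in panel.dna_targets:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\ttarget\n")
        for iv in panel.control_targets:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tcontrol\n")


def export_locus_fasta(panel: PanelConfig, path: str | Path) -> None:
    """Write the locus and control sequences as FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in panel.sequences().items()
    ]
    SeqIO.write(records, str(path), "fasta")
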