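"""Upstream-kinase calling by dual-database consensus.

Each array peptide is a 13-mer around known phosphotyrosines of a human
protein, identified as ``PROTEIN_start_end`` (1-based inclusive residue
range).  Two independent kinase-substrate annotation databases each propose
candidate upstream kinases per peptide; a kinase is *positively identified*
only when both sources agree (set intersection after normalizing spelling:
uppercase plus an alias table folding e.g. HER4 onto ERBB4).  Consensus
kinases are then partitioned across the peptide activity clusters into Venn
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .io import KinaseAnnotationSource, normalize_kinase_name

__all__ = [
    "PeptideIdentifier",
    "ConsensusCall",
    "VennPartition",
    "parse_peptide_id",
    "load_aliases",
    "consensus_upstream_kinases",
    "consensus_table",
    "venn_partition",
]


@dataclass(frozen=True)
class PeptideIdentifier:
    raw: str
    protein: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid residue range in {self.raw!r}")
        if self.raw != f"{self.protein}_{self.start}_{self.end}":
            raise ValueError(f"{self.raw!r} does not reconstruct from its fields")


@dataclass(frozen=True)
class ConsensusCall:
    peptide: PeptideIdentifier
    source_a_kinases: frozenset[str]
    source_b_kinases: frozenset[str]
    consensus: frozenset[str]
    annotated: bool  # False when the peptide is absent from both sources

    def __post_init__(self) -> None:
        if not self.consensus <= (self.source_a_kinases & self.source_b_kinases):
            raise ValueError("consensus must be contained in both sources")


@dataclass
class VennPartition:
    """Disjoint regions mapping each kinase to the exact set of peptide
    clusters in which it was called."""

    regions: dict[frozenset[str], set[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for region, kinases in self.regions.items():
            overlap = seen & kinases
            if overlap:
                raise ValueError(f"kinases {sorted(overlap)} appear in multiple regions")
            seen |= kinases

    def region_of(self, kinase: str) -> frozenset[str] | None:
        for region, kinases in self.regions.items():
            if kinase in kinases:
                return region
        return None

    @property
    def all_kinases(self) -> set[str]:
        out: set[str] = set()
        for kinases in self.regions.values():
            out |= kinases
        return out


def parse_peptide_id(raw: str) -> PeptideIdentifier:
    """Split ``PROTEIN_start_end``; the protein token may contain underscores."""
    if not raw:
        raise ValueError("empty peptide id")
    parts = raw.split("_")
    if len(parts) < 3:
        raise ValueError(f"cannot parse peptide id {raw!r}: need PROTEIN_start_end")
    try:
        start, end = int(parts[-2]), int(parts[-1])
    except ValueError as err:
        raise ValueError(f"cannot parse residue range in {raw!r}") from err
    protein = "_".join(parts[:-2])
    if not protein:
        raise ValueError(f"empty protein token in {raw!r}")
    return PeptideIdentifier(raw=raw, protein=protein, start=start, end=end)


def load_aliases(path: str | Path | None = None) -> dict[str, str]:
    """Load the kinase alias table (alias -> canonical symbol), uppercased.

    The shipped table covers the spelling divergences between the two
    annotation sources on the 144-peptide PTK panel (HER4/ERBB4, Abl/ABL1,
    Ron/MST1R, FAK/PTK2, ...); users may point at an extended TSV.
    """
    if path is None:
        ref = resources.files("kinact").joinpath("data/kinase_aliases.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    aliases: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("alias\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"alias table line {lineno}: expected alias<TAB>canonical")
        aliases[parts[0].strip().upper()] = parts[1].strip().upper()
    return aliases


def consensus_upstream_kinases(
    peptide: str | PeptideIdentifier,
    source_a: KinaseAnnotationSource,
    source_b: KinaseAnnotationSource,
    aliases: Mapping[str, str] | None = None,
) -> ConsensusCall:
    """Kinases proposed by *both* sources for one peptide.

    An empty consensus is a valid outcome; a peptide absent from both sources
    is returned with ``annotated=False``.
    """
    pid = peptide if isinstance(peptide, PeptideIdentifier) else parse_peptide_id(peptide)
    if aliases is None:
        aliases = load_aliases()
    raw_a = source_a.get(pid.raw)
    raw_b = source_b.get(pid.raw)
    annotated = raw_a is not None or raw_b is not None
    set_a = frozenset(normalize_kinase_name(k, aliases) for k in (raw_a or ()))
    set_b = frozenset(normalize_kinase_name(k, aliases) for k in (raw_b or ()))
    return ConsensusCall(
        peptide=pid,
        source_a_kinases=set_a,
        source_b_kinases=set_b,
        consensus=set_a & set_b,
        annotated=annotated,
    )


def consensus_table(
    peptides: Iterable[str],
    source_a: KinaseAnnotationSource,
    source_b: KinaseAnnotationSource,
    aliases: Mapping[str, str] | None = None,
) -> list[ConsensusCall]:
    if aliases is None:
        aliases = load_aliases()
    return [consensus_upstream_kinases(p, source_a, source_b, aliases) for p in peptides]


def load_ptk_panel() -> tuple[KinaseAnnotationSource, KinaseAnnotationSource, dict[str, str]]:
    """Shipped annotation snapshot for 36 peptides of the 144-peptide PTK panel.

    Returns the UniProt-derived source, the PhosphoSitePlus-derived source
    (names as each database spells them; normalization happens at consensus
    time) and the peptide activity-cluster labels.
    """
    from .io import read_kinase_db  # local import to keep module load light

    data = resources.files("kinact").joinpath("data")
    with resources.as_file(data.joinpath("ptk_panel_uniprot.tsv")) as p:
        uniprot = read_kinase_db(p, source_name="uniprot")
    with resources.as_file(data.joinpath("ptk_panel_phosphositeplus.tsv")) as p:
        psp = read_kinase_db(p, source_name="phosphositeplus")
    clusters: dict[str, str] = {}
    for line in data.joinpath("ptk_panel_clusters.tsv").read_text().splitlines()[1:]:
        if line.strip():
            pep, cluster = line.split("\t")
            clusters[pep] = cluster
    return uniprot, psp, clusters


def venn_partition(
    calls: Iterable[ConsensusCall],
    peptide_clusters: Mapping[str, str],
) -> VennPartition:
    """Assign each consensus kinase to the exact set of peptide clusters that
    contain at least one peptide whose consensus includes it."""
    clusters_of: dict[str, set[str]] = {}
    for call in calls:
        try:
            cluster = peptide_clusters[call.peptide.raw]
        except KeyError as err:
            raise ValueError(f"peptide {call.peptide.raw!r} has no cluster label") from err
        for kinase in call.consensus:
            clusters_of.setdefault(kinase, set()).add(str(cluster))
    regions: dict[frozenset[str], set[str]] = {}
    for kinase, clusters in clusters_of.items():
        regions.setdefault(frozenset(clusters), set()).add(kinase)
    return VennPartition(regions=regions)
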