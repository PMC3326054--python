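"""Readers, writers, configuration and fixture generation.

File conventions: count tables are taxa-as-rows TSV (human-diffable), trees
are Newick with branch lengths, community specs are YAML, reads go to FASTA
or FASTQ with ``taxon=<id>;mid=<seq>`` carried in the record description.
All writers emit newline-terminated UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

from .community import CommunitySpec, Taxon, mock_community
from .otu_table import OTUTable
from .simulate import AmpliconLibrary, simulate_library

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_community_spec",
    "write_community_spec",
    "read_tree",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_library_fasta",
    "write_library_fastq",
    "library_counts_table",
    "generate_fixtures",
    "RunConfig",
]


# -- OTU tables ---------------------------------------------------------

def read_otu_table(path: str | Path) -> OTUTable:
    """Read a taxa-as-rows TSV count table (see :meth:`OTUTable.from_tsv`)."""
    return OTUTable.from_tsv(path)


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    table.to_tsv(path)


# -- community specs ----------------------------------------------------

def write_community_spec(spec: CommunitySpec, path: str | Path) -> None:
    """Serialize a community spec to YAML (abundances, copy numbers,
    reference amplicons)."""
    payload = {
        "taxa": [
            {
                "taxon_id": t.taxon_id,
                "genus": t.genus,
                "input_abundance": t.input_abundance,
                "copy_number": t.copy_number,
                "reference_amplicon": t.reference_amplicon,
            }
            for t in spec.taxa
        ]
    }
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=False), encoding="utf-8"
    )


def read_community_spec(path: str | Path) -> CommunitySpec:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, dict) or "taxa" not in payload:
        raise ValueError(f"{path}: expected a mapping with a 'taxa' list")
    allowed = {
        "taxon_id",
        "genus",
        "input_abundance",
        "copy_number",
        "reference_amplicon",
    }
    taxa = []
    for entry in payload["taxa"]:
        unknown = set(entry) - allowed
        if unknown:
            raise ValueError(
                f"{path}: unknown keys in taxon entry: {sorted(unknown)}"
            )
        taxa.append(Taxon(**entry))
    return CommunitySpec(taxa=taxa)


# -- trees and distance matrices ---------------------------------------

def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; branch lengths are required downstream.

    Underscores in leaf labels are kept verbatim (taxon ids routinely use
    them), overriding the newick convention of reading them as spaces.
    """
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = dm.to_data_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


# -- simulated reads ----------------------------------------------------

def _records(library: AmpliconLibrary, quality: int | None = None):
    for i, read in enumerate(library.reads):
        rec = SeqRecord(
            Seq(read.mid + read.sequence),
            id=f"read_{i:06d}",
            description=f"taxon={read.true_taxon};mid={read.mid}",
        )
        if quality is not None:
            rec.letter_annotations["phred_quality"] = [quality] * len(rec)
        yield rec


def write_library_fasta(library: AmpliconLibrary, path: str | Path) -> None:
    """Write reads (MID prepended) as FASTA; headers carry taxon and MID."""
    SeqIO.write(_records(library), str(path), "fasta")


def write_library_fastq(
    library: AmpliconLibrary, path: str | Path, quality: int = 40
) -> None:
    """FASTQ with a constant Phred quality (simulated reads carry no
    per-base quality model)."""
    SeqIO.write(_records(library, quality), str(path), "fastq")


def library_counts_table(
    libraries: dict[str, AmpliconLibrary], spec: CommunitySpec
) -> OTUTable:
    """Ground-truth count table from simulated libraries (taxa x samples)."""
    df = pd.DataFrame(
        {name: lib.counts for name, lib in libraries.items()}
    ).reindex(spec.taxon_ids).fillna(0)
    genus = {t.taxon_id: t.genus for t in spec.taxa}
    return OTUTable(counts=df, genus=genus)


# -- fixtures -----------------------------------------------------------

def genus_tree(spec: CommunitySpec) -> TreeNode:
    """A star-like genus-level tree over the spec's taxa.

    Taxa sharing a genus sit on a common unit-length internal branch with
    short tip branches; singleton genera attach directly to the root.  A
    stand-in for a reference phylogeny: adequate for validating distance
    algebra, not for reproducing published distances.
    """
    by_genus: dict[str, list[str]] = {}
    for t in spec.taxa:
        by_genus.setdefault(t.genus, []).append(t.taxon_id)
    parts = []
    for genus, members in sorted(by_genus.items()):
        if len(members) == 1:
            parts.append(f"{members[0]}:1.0")
        else:
            inner = ",".join(f"{m}:0.25" for m in members)
            parts.append(f"({inner}){genus}:0.75")
    newick = f"({','.join(parts)})root;"
    return TreeNode.read([newick], format="newick", convert_underscores=False)


def generate_fixtures(seed: int, outdir: str | Path) -> Path:
    """Write the self-contained fixture set used by tests and examples.

    Produces the twelve-taxon mock-community spec (YAML, synthetic reference
    amplicons), a genus-level Newick tree, two simulated 5,000-read libraries
    with FASTA reads, and their ground-truth count table as TSV.  Re-running
    with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = mock_community()
    write_community_spec(spec, outdir / "mock_community.yaml")
    tree = genus_tree(spec)
    tree.write(str(outdir / "genus_tree.nwk"))
    libraries = {}
    for rep in (1, 2):
        lib = simulate_library(spec, n_reads=5000, seed=seed + rep)
        libraries[f"insilico_{rep}"] = lib
        write_library_fasta(lib, outdir / f"insilico_{rep}.fasta")
    table = library_counts_table(libraries, spec)
    write_otu_table(table, outdir / "truth_counts.tsv")
    return outdir


# -- run configuration --------------------------------------------------

_KNOWN_BLOCKS = {"seed", "paths", "simulator", "detection", "filter", "compare"}


@dataclass
class RunConfig:
    """Resolved configuration for :func:`amplimit.pipeline.run_pipeline`.

    Unknown top-level keys are rejected so typos fail loudly; the resolved
    config is echoed into the output directory for provenance.
    """

    seed: int = 0
    paths: dict = dataclass_field(default_factory=dict)
    simulator: dict = dataclass_field(default_factory=dict)
    detection: dict = dataclass_field(default_factory=dict)
    filter: dict = dataclass_field(default_factory=dict)
    compare: dict = dataclass_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(payload) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("spec", "tree"):
            ref = payload.get("paths", {}).get(key)
            if ref and not Path(ref).exists():
                raise FileNotFoundError(f"{path}: missing input file {ref}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "paths": self.paths,
            "simulator": self.simulator,
            "detection": self.detection,
            "filter": self.filter,
            "compare": self.compare,
        }
        Path(path).write_text(
            yaml.safe_dump(payload, sort_keys=False), encoding="utf-8"
        )
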