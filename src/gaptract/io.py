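"""File formats: FASTA sequences, BED-like interval tables, call tables.

Internal coordinates are 0-based half-open with an explicit ``wraps``
column for origin-crossing circular intervals (standard BED cannot express
wrap). The call table is a minimal VCF-like TSV with 1-based POS, per VCF
convention; everything in memory stays 0-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calls import CloneCallSet
from .intervals import CircularInterval
from .simulate import CloneSequence, GapSet
from .substrate import PlasmidSubstrate
from .tracts import CloneClassification, Tract


# -- FASTA -------------------------------------------------------------------

def write_clones_fasta(clones: Sequence[CloneSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.clone_id, description="") for c in clones]
    SeqIO.write(records, str(path), "fasta")


def read_clones_fasta(path: str | Path) -> list[CloneSequence]:
    return [CloneSequence(clone_id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_substrate(substrate: PlasmidSubstrate, fasta_path: str | Path,
                    annotation_path: str | Path) -> None:
    """FASTA sequence plus YAML sidecar with nick/mispair/site annotations."""
    SeqIO.write(
        [SeqRecord(Seq(substrate.sequence_nicked_strand), id=substrate.name,
                   description="circular nicked-strand 5'->3'")],
        str(fasta_path), "fasta")
    ann = {
        "name": substrate.name,
        "circular": True,
        "nick_position": substrate.nick_position,
        "nick_side": substrate.nick_side,
        "mispair_position": substrate.mispair_position,
        "mispair_type": substrate.mispair_type,
        "enzyme_sites": {e: list(map(int, ps)) for e, ps in substrate.enzyme_sites.items()},
        "mispair_readout": dict(substrate.mispair_readout),
        "protected_intervals": [
            {"start": iv.start, "end": iv.end, "wraps": iv.wraps}
            for iv in substrate.protected_intervals
        ],
    }
    Path(annotation_path).write_text(yaml.safe_dump(ann, sort_keys=False))


def read_substrate(fasta_path: str | Path, annotation_path: str | Path) -> PlasmidSubstrate:
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    ann = yaml.safe_load(Path(annotation_path).read_text())
    return PlasmidSubstrate(
        name=ann.get("name", rec.id),
        sequence_nicked_strand=str(rec.seq).upper(),
        nick_position=int(ann["nick_position"]),
        nick_side=ann["nick_side"],
        mispair_position=int(ann["mispair_position"]),
        mispair_type=ann.get("mispair_type", "plusT"),
        enzyme_sites={e: list(map(int, ps)) for e, ps in ann.get("enzyme_sites", {}).items()},
        mispair_readout=dict(ann.get("mispair_readout", {})),
        protected_intervals=[
            CircularInterval(int(d["start"]), int(d["end"]))
            for d in ann.get("protected_intervals", [])
        ],
    )


# -- BED-like interval tables ------------------------------------------------

def gapsets_to_bed(gapsets: Iterable[GapSet], name: str = "truth") -> pd.DataFrame:
    rows = []
    for gs in gapsets:
        for g, tag in zip(gs.gaps, gs.origin_tags):
            rows.append({"chrom": name, "start": g.start, "end": g.end,
                         "wraps": int(g.wraps), "molecule": gs.molecule_id,
                         "origin": tag})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "wraps",
                                       "molecule", "origin"])


def bed_to_gapsets(frame: pd.DataFrame) -> list[GapSet]:
    out: dict[str, GapSet] = {}
    for row in frame.itertuples(index=False):
        gs = out.setdefault(row.molecule, GapSet(molecule_id=row.molecule))
        gs.gaps.append(CircularInterval(int(row.start), int(row.end)))
        gs.origin_tags.append(row.origin)
    return list(out.values())


def tracts_to_bed(tracts_by_clone: Mapping[str, Sequence[Tract]],
                  classifications: Mapping[str, CloneClassification],
                  name: str = "tracts") -> pd.DataFrame:
    rows = []
    for clone_id, tracts in tracts_by_clone.items():
        label = classifications[clone_id].label if clone_id in classifications else ""
        for t in tracts:
            rows.append({
                "chrom": name, "start": t.span.start, "end": t.span.end,
                "wraps": int(t.span.wraps), "clone": clone_id,
                "n_events": t.n_events,
                "n_skipped": len(t.skipped_cytidines),
                "label": label,
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "wraps", "clone",
                                       "n_events", "n_skipped", "label"])


def classifications_to_frame(classifications: Iterable[CloneClassification]) -> pd.DataFrame:
    rows = [{
        "clone": c.clone_id, "label": c.label, "n_tracts": c.n_tracts,
        "longest_tract_nt": c.longest_tract_nt,
        "distance_first_event_to_nick": c.distance_first_event_to_nick,
    } for c in classifications]
    return pd.DataFrame(rows, columns=["clone", "label", "n_tracts",
                                       "longest_tract_nt", "distance_first_event_to_nick"])


# -- VCF-like call table -----------------------------------------------------

def calls_to_frame(callsets: Iterable[CloneCallSet], plasmid_name: str) -> pd.DataFrame:
    """Minimal VCF-like table: 1-based POS in output, 0-based in memory."""
    rows = []
    for cs in callsets:
        for e in cs.events:
            rows.append({
                "CHROM": plasmid_name, "POS": e.position + 1,
                "REF": e.ref_base, "ALT": e.alt_base,
                "INFO": f"strand_class={e.strand_class.value}",
                "clone": cs.clone_id, "qc_excluded": int(cs.qc_excluded),
            })
    return pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT", "INFO",
                                       "clone", "qc_excluded"])


# -- Manifests ---------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, config: Mapping, outputs: Mapping[str, str | Path]) -> dict:
    manifest = {
        "config": json.loads(json.dumps(config, default=str)),
        "outputs": {k: {"path": str(p), "sha256": file_sha256(p)}
                    for k, p in outputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
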