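#!/usr/bin/env python
"""Rebuild the focal element's consensus and annotate its anatomy.

Reports the majority-rule consensus over all genomic copies, its open
reading frames, terminal inverted repeats, and the mariner transposase
motifs (DD34D catalytic spacing, C-terminal YSPDLAP); features are also
written as GFF3 on the consensus.
"""
import argparse
import json
from pathlib import Path

from tehop.anatomy import (build_consensus, find_orfs, find_tirs,
                           scan_mariner_motifs)
from tehop.simulate import default_config, simulate_world

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    world = simulate_world(default_config(seed=args.seed,
                                          include_brother_pairs=False))
    args.out.mkdir(parents=True, exist_ok=True)
    report = {}
    gff = ["##gff-version 3"]
    for sp, fam in sorted(world.te.items()):
        cons = build_consensus([fam.copies[c] for c in sorted(fam.copies)])
        if cons.status != "ok":
            report[sp] = {"status": cons.status}
            continue
        orfs = find_orfs(cons.consensus, min_len_nt=300)
        tir = find_tirs(cons.consensus)
        motifs = scan_mariner_motifs(orfs[0].translation) if orfs else None
        report[sp] = {
            "status": "ok", "consensus_length": len(cons.consensus),
            "n_fragments": cons.n_fragments_used,
            "longest_orf_nt": orfs[0].length_nt if orfs else 0,
            "tir_identity": None if tir is None else round(tir.identity, 3),
            "dd34d": bool(motifs and motifs.dd34d),
            "yspdlap": bool(motifs and motifs.yspdlap),
        }
        seqid = f"{sp}_consensus"
        if orfs:
            o = orfs[0]
            gff.append(f"{seqid}\ttehop\tORF\t{o.start+1}\t{o.end}\t.\t"
                       f"{o.strand}\t.\tID=orf_{sp}")
        if tir:
            for tag, (s, e) in (("tir_left", tir.left), ("tir_right", tir.right)):
                gff.append(f"{seqid}\ttehop\tinverted_repeat\t{s+1}\t{e}\t.\t"
                           f"+\t.\tID={tag}_{sp}")
    (args.out / "anatomy.json").write_text(json.dumps(report, indent=1,
                                                      sort_keys=True))
    (args.out / "anatomy.gff3").write_text("\n".join(gff) + "\n")
    print(json.dumps(report, indent=1, sort_keys=True))
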