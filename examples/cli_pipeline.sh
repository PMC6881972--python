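#!/bin/sh
# End-to-end shell pipeline on a small simulated study:
# simulate -> build-bins -> compare -> cluster -> evaluate.
# Run from the repository root:  sh examples/cli_pipeline.sh
set -e

OUT=$(mktemp -d)
trap 'rm -rf "$OUT"' EXIT

afmeta simulate --mode group --n-genomes 8 --n-groups 2 --replicates 3 \
    --depth 2000 --genome-length 20000 --seed 7 --out "$OUT/sim"

afmeta build-bins "$OUT/sim/genomes.fasta" \
    --genome-map "$OUT/sim/genome_ids.tsv" -C 2 --order 1 \
    --out "$OUT/bins"

# lexicographic sort interleaves each sample's _R1/_R2 pair
afmeta compare $(ls "$OUT"/sim/*_R[12].fastq.gz | sort) \
    --paired --bin-set "$OUT/bins" -k 5 --background-order 1 \
    --out "$OUT/d2s.tsv"

afmeta cluster "$OUT/d2s.tsv" --out "$OUT/tree.nwk"
afmeta evaluate --tree "$OUT/tree.nwk" --truth "$OUT/sim/truth.tsv"
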