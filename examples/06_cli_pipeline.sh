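#!/bin/sh
# Full shell pipeline: simulate -> segment -> back-fit -> test.
# Every output gets a .json sidecar recording parameters and seed.
set -e
out=$(mktemp -d)

eegtopo --seed 7 simulate microstates --frames 2000 --out "$out/sim"
eegtopo --seed 7 segment --input "$out/sim/recording.eph" \
    --q 2:6 --restarts 8 --out "$out/seg"
eegtopo fit --templates "$out/seg/templates.eph" \
    --inputs "$out/sim/recording.eph" --out "$out/fit.csv"
eegtopo measures --input "$out/sim/recording.eph" \
    --out "$out/gfp.csv,$out/gmd.csv"

echo "criteria table:"
cat "$out/seg/criteria.csv"
echo "outputs in $out"
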