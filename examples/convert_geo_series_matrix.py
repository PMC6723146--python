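"""NON-VALIDATED convenience converter for real Agilent two-color arrays.

The published GMR analyses used Agilent 4x44k two-color arrays deposited
in GEO (series GSE72304, GSE97001, GSE97002, GSE133891, GSE133906,
GSE97031, GSE97028, GSE97030, GSE97427, GSE72333, GSE72414, GSE72415).
This script converts *locally downloaded* Agilent Feature Extraction
text exports (one file per biological replicate, as found in those
series' supplementary files) into the probe-table TSV this package
reads.  It is an unsupported example, NOT part of the tested interface:

* it has NOT been validated against the published GCH tables — those
  depend on an unpublished lab normalization protocol, so numbers
  produced this way are not expected to reproduce published values;
* column conventions vary between Feature Extraction versions; adjust
  the FG/BG/flag column names below to your files.

Usage:
    python convert_geo_series_matrix.py rep1.txt rep2.txt rep3.txt rep4.txt \
        --out probes.tsv
Then:
    gmr rank --input probes.tsv --outdir results/
"""

import argparse
import csv
import sys

FG_COLUMN = "gMedianSignal"       # single-channel green foreground
BG_COLUMN = "gBGMedianSignal"     # local background
OK_COLUMN = "gIsWellAboveBG"      # used here as the pixel-quality proxy
PROBE_COLUMN = "ProbeName"
GENE_COLUMN = "GeneName"
CONTROL_COLUMN = "ControlType"    # non-zero = control spot


def read_feature_extraction(path):
    """Yield dicts from the FEATURES block of an Agilent FE text export."""
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = None
        for row in reader:
            if not row:
                continue
            if row[0] == "FEATURES":
                header = row
                continue
            if header and row[0] == "DATA":
                yield dict(zip(header, row))


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("replicates", nargs="+",
                        help="Feature Extraction text file per replicate (>=4)")
    parser.add_argument("--out", required=True)
    args = parser.parse_args()
    if len(args.replicates) < 4:
        sys.exit("need at least 4 biological replicates")

    tables = []
    for path in args.replicates:
        table = {}
        for rec in read_feature_extraction(path):
            table[rec[PROBE_COLUMN]] = rec
        if not table:
            sys.exit(f"{path}: no FEATURES/DATA block found - is this an "
                     "Agilent Feature Extraction export?")
        tables.append(table)

    common = set(tables[0])
    for table in tables[1:]:
        common &= set(table)

    n = len(args.replicates)
    header = ["probe_id", "gene_id", "is_control"]
    for k in range(1, n + 1):
        header += [f"fg_{k}", f"bg_{k}", f"ok_{k}"]
    with open(args.out, "w") as out:
        out.write("\t".join(header) + "\n")
        for probe in sorted(common):
            first = tables[0][probe]
            row = [probe, first[GENE_COLUMN],
                   "1" if first.get(CONTROL_COLUMN, "0") != "0" else "0"]
            for table in tables:
                rec = table[probe]
                row += [rec[FG_COLUMN], rec[BG_COLUMN],
                        rec.get(OK_COLUMN, "1")]
            out.write("\t".join(row) + "\n")
    print(f"wrote {len(common)} probes x {n} replicates to {args.out} "
          "(non-validated conversion - see header notes)")


if __name__ == "__main__":
    main()
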