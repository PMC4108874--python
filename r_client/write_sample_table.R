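#!/usr/bin/env Rscript
# Fetch an experiment from a semexp endpoint by DESCRIBE traversal and write
# its sample table as TSV.
#
# Usage: Rscript write_sample_table.R <endpoint-url> <experiment-uri> <out.tsv>
# The SEMEXP_API_KEY environment variable, when set, selects the admin tier.

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 3) {
  stop("usage: write_sample_table.R <endpoint-url> <experiment-uri> <out.tsv>")
}
script_dir <- dirname(sub("--file=", "", grep("--file=", commandArgs(), value = TRUE)[1]))
source(file.path(script_dir, "semexp_client.R"))

record <- fetch_experiment(args[[1]], args[[2]])
con <- file(args[[3]], open = "wb")
writeChar(sample_frame_tsv(record), con, eos = NULL, useBytes = TRUE)
close(con)
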