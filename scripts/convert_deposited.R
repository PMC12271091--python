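#!/usr/bin/env Rscript
# Convert deposited multivariable-LDSC output (an .RData/.rds file holding a
# list with elements S and V, as produced by the genomic SEM toolchain) into
# the delimited matrices this package consumes:
#
#   Rscript scripts/convert_deposited.R input.RData data/deposited/matrices \
#       [rename.json]
#
# writes <prefix>.S.tsv, <prefix>.V.tsv and <prefix>.json.  The optional
# rename.json maps the trait labels stored in the file onto the canonical
# labels (NU, PU, PREMED, ATT, MOTOR, NONPLAN, PAU, CUD, OUD, TUD, DD, SS,
# PERSEV, AN).  V is assumed to follow the usual half-vectorization of S
# (column-major over the lower triangle), which is also this package's
# frozen convention.

args <- commandArgs(trailingOnly = TRUE)
if (length(args) < 2) stop("usage: convert_deposited.R input prefix [rename.json]")
input <- args[[1]]
prefix <- args[[2]]

load_obj <- function(path) {
  if (grepl("\\.rds$", path, ignore.case = TRUE)) return(readRDS(path))
  env <- new.env()
  load(path, envir = env)
  for (nm in ls(env)) {
    obj <- get(nm, envir = env)
    if (is.list(obj) && !is.null(obj$S) && !is.null(obj$V)) return(obj)
  }
  stop("no object with $S and $V found in ", path)
}

obj <- load_obj(input)
S <- as.matrix(obj$S)
V <- as.matrix(obj$V)
labels <- colnames(S)
if (is.null(labels)) stop("S has no column names; supply them manually")
message("trait labels found: ", paste(labels, collapse = ", "))

if (length(args) >= 3) {
  rename <- jsonlite::fromJSON(args[[3]])
  labels <- ifelse(labels %in% names(rename), unlist(rename[labels]), labels)
}

dir.create(dirname(prefix), recursive = TRUE, showWarnings = FALSE)
rownames(S) <- colnames(S) <- labels
write.table(S, paste0(prefix, ".S.tsv"), sep = "\t", quote = FALSE,
            col.names = NA)
write.table(V, paste0(prefix, ".V.tsv"), sep = "\t", quote = FALSE,
            row.names = FALSE, col.names = FALSE)
meta <- list(traits = labels,
             vech_order = "column-major lower triangle",
             n_blocks = NULL, smoothed = FALSE)
writeLines(jsonlite::toJSON(meta, auto_unbox = TRUE, null = "null",
                            pretty = TRUE),
           paste0(prefix, ".json"))
message("wrote ", prefix, ".{S.tsv,V.tsv,json}")
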