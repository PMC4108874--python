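# Thin R client for a semexp SPARQL endpoint.
#
# The client speaks HTTP + SPARQL JSON results only: no local RDF parsing,
# and UTF-8 is forced end to end.  An experiment record is rebuilt purely
# by DESCRIBE-based traversal (experiment -> assays -> replicates ->
# biomaterials -> terms), exactly mirroring the Python library's
# describe_traverse, and flattened into an analysis-ready sample table
# (one row per replicate) whose TSV rendering is byte-identical to the
# Python side's.
#
# Exported functions:
#   fetch_experiment(endpoint, experiment_uri, api_key = NULL) -> nested list
#   sample_frame(record)      -> data.frame, one row per replicate
#   sample_frame_tsv(record)  -> single TSV string
#
# The endpoint/key may also come from the SEMEXP_ENDPOINT / SEMEXP_API_KEY
# environment variables.

library(jsonlite)

# Predicate URIs of the default mapping registry.
.P <- list(
  title        = "http://purl.org/dc/terms/title",
  description  = "http://purl.org/dc/terms/description",
  created      = "http://purl.org/dc/terms/created",
  modified     = "http://purl.org/dc/terms/modified",
  has_part     = "http://purl.org/obo/owl/ro#has_part",
  replicates   = "http://purl.obolibrary.org/obo/OBI_0000293",
  biomaterial  = "http://purl.org/obo/owl/ro#is_a",
  rep_type     = "http://example.org/semexp/ns#replicate_type",
  platform     = "http://example.org/semexp/ns#platform",
  raw_file     = "http://example.org/semexp/ns#raw_data_file",
  label        = "http://www.w3.org/2000/01/rdf-schema#label",
  preferred_eq = "http://purl.org/ontology/ao/core#preferred_equivalent"
)

.ANNOTATION_ATTRS <- c(
  organism            = "http://purl.obolibrary.org/obo/OBI_0100026",
  developmental_stage = "http://www.ebi.ac.uk/efo/EFO_0000399",
  tissue              = "http://purl.obolibrary.org/obo/UBERON_0001062",
  cell_type           = "http://purl.obolibrary.org/obo/CL_0000000",
  cell_line           = "http://purl.obolibrary.org/obo/CLO_0000031",
  disease_state       = "http://purl.obolibrary.org/obo/DOID_4",
  treatment           = "http://purl.obolibrary.org/obo/CHEBI_24431"
)

.http_get_json <- function(full_url, api_key = NULL) {
  headers <- c(Accept = "application/sparql-results+json")
  if (!is.null(api_key)) headers <- c(headers, "X-API-Key" = api_key)
  con <- url(full_url, headers = headers)
  on.exit(close(con), add = TRUE)
  txt <- paste(readLines(con, warn = FALSE, encoding = "UTF-8"), collapse = "\n")
  fromJSON(txt, simplifyVector = FALSE)
}

# DESCRIBE a URI; returns a named list predicate -> sorted character vector
# of object values.  Auth failures and HTTP errors surface as R errors.
.describe <- function(endpoint, uri, api_key = NULL) {
  q <- sprintf("DESCRIBE <%s>", uri)
  full <- sprintf("%s/sparql?query=%s", sub("/$", "", endpoint),
                  URLencode(q, reserved = TRUE))
  res <- tryCatch(.http_get_json(full, api_key), error = function(e) {
    stop(sprintf("endpoint request failed for %s: %s", uri, conditionMessage(e)))
  })
  if (!is.null(res$error)) stop(sprintf("endpoint error: %s", res$error))
  out <- list()
  for (b in res$results$bindings) {
    p <- b$p$value
    out[[p]] <- c(out[[p]], b$o$value)
  }
  lapply(out, function(v) sort(v, method = "radix"))
}

.first <- function(d, pred) {
  v <- d[[pred]]
  if (is.null(v) || length(v) == 0) "" else v[[1]]
}

fetch_experiment <- function(endpoint = Sys.getenv("SEMEXP_ENDPOINT"),
                             experiment_uri,
                             api_key = NULL) {
  if (is.null(api_key) && nzchar(Sys.getenv("SEMEXP_API_KEY")))
    api_key <- Sys.getenv("SEMEXP_API_KEY")
  exp_d <- .describe(endpoint, experiment_uri, api_key)
  if (length(exp_d) == 0)
    stop(sprintf("no such resource in store: %s", experiment_uri))

  term_cache <- new.env()
  term_record <- function(term_uri) {
    if (!exists(term_uri, envir = term_cache)) {
      d <- .describe(endpoint, term_uri, api_key)
      assign(term_uri, list(uri = term_uri,
                            label = .first(d, .P$label),
                            class_uri = .first(d, .P$preferred_eq)),
             envir = term_cache)
    }
    get(term_uri, envir = term_cache)
  }

  biomaterial_record <- function(bm_uri) {
    d <- .describe(endpoint, bm_uri, api_key)
    annotations <- list()
    for (attr in names(.ANNOTATION_ATTRS)) {
      term_uris <- d[[.ANNOTATION_ATTRS[[attr]]]]
      if (!is.null(term_uris) && length(term_uris) > 0)
        annotations[[attr]] <- term_record(term_uris[[1]])
    }
    list(uri = bm_uri, name = .first(d, .P$title), annotations = annotations)
  }

  assays <- list()
  for (assay_uri in sort(exp_d[[.P$has_part]], method = "radix")) {
    a_d <- .describe(endpoint, assay_uri, api_key)
    replicates <- list()
    for (rep_uri in sort(a_d[[.P$replicates]], method = "radix")) {
      r_d <- .describe(endpoint, rep_uri, api_key)
      bm_uri <- .first(r_d, .P$biomaterial)
      replicates[[length(replicates) + 1]] <- list(
        uri = rep_uri,
        replicate_type = .first(r_d, .P$rep_type),
        biomaterial = if (nzchar(bm_uri)) biomaterial_record(bm_uri) else NULL
      )
    }
    assays[[length(assays) + 1]] <- list(
      uri = assay_uri,
      name = .first(a_d, .P$title),
      platform = .first(a_d, .P$platform),
      raw_data_files = as.list(if (is.null(a_d[[.P$raw_file]])) character(0) else a_d[[.P$raw_file]]),
      replicates = replicates
    )
  }

  list(uri = experiment_uri,
       title = .first(exp_d, .P$title),
       description = .first(exp_d, .P$description),
       created = .first(exp_d, .P$created),
       modified = .first(exp_d, .P$modified),
       assays = assays)
}

.SAMPLE_COLUMNS <- c("assay", "replicate", "replicate_type", "biomaterial",
                     as.vector(rbind(names(.ANNOTATION_ATTRS),
                                     paste0(names(.ANNOTATION_ATTRS), "_uri"))))

.local_id <- function(uri) {
  parts <- strsplit(sub("/$", "", uri), "/", fixed = TRUE)[[1]]
  parts[[length(parts)]]
}

.sample_rows <- function(record) {
  rows <- list()
  for (assay in record$assays) {
    for (rep in assay$replicates) {
      bm <- if (is.null(rep$biomaterial)) list(name = "", annotations = list()) else rep$biomaterial
      row <- c(.local_id(assay$uri), .local_id(rep$uri), rep$replicate_type, bm$name)
      for (attr in names(.ANNOTATION_ATTRS)) {
        ann <- bm$annotations[[attr]]
        row <- c(row, if (is.null(ann)) c("", "") else c(ann$label, ann$class_uri))
      }
      rows[[length(rows) + 1]] <- row
    }
  }
  rows
}

sample_frame <- function(record) {
  rows <- .sample_rows(record)
  df <- as.data.frame(do.call(rbind, c(rows, list(deparse.level = 0))),
                      stringsAsFactors = FALSE)
  if (length(rows) == 0)
    df <- as.data.frame(matrix(character(0), ncol = length(.SAMPLE_COLUMNS)),
                        stringsAsFactors = FALSE)
  names(df) <- .SAMPLE_COLUMNS
  df
}

sample_frame_tsv <- function(record) {
  lines <- c(paste(.SAMPLE_COLUMNS, collapse = "\t"),
             vapply(.sample_rows(record), paste, "", collapse = "\t"))
  paste0(paste(lines, collapse = "\n"), "\n")
}
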