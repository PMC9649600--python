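#!/usr/bin/env Rscript
# Frozen DESeq2 driver for the scnoise bridge.
# Usage: Rscript deseq2_bridge.R counts.tsv labels.tsv out.tsv groupA groupB
# counts.tsv: feature_id in first column, cells in remaining columns.
# labels.tsv: columns cell_id, group. Contrast reported is groupB over groupA.

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 5) {
  stop("expected: counts.tsv labels.tsv out.tsv groupA groupB")
}
counts_path <- args[1]
labels_path <- args[2]
out_path <- args[3]
group_a <- args[4]
group_b <- args[5]

suppressMessages(library(DESeq2))

counts <- read.table(counts_path, header = TRUE, sep = "\t",
                     row.names = 1, check.names = FALSE)
labels <- read.table(labels_path, header = TRUE, sep = "\t",
                     check.names = FALSE, colClasses = "character")
counts <- counts[, labels$cell_id, drop = FALSE]
coldata <- data.frame(group = factor(labels$group, levels = c(group_a, group_b)),
                      row.names = labels$cell_id)

dds <- DESeqDataSetFromMatrix(countData = as.matrix(counts),
                              colData = coldata, design = ~group)
dds <- DESeq(dds, quiet = TRUE)
res <- results(dds, contrast = c("group", group_b, group_a))

out <- data.frame(gene = rownames(res),
                  baseMean = res$baseMean,
                  log2FC = res$log2FoldChange,
                  se = res$lfcSE,
                  wald_p = res$pvalue,
                  padj = res$padj)
write.table(out, out_path, sep = "\t", quote = FALSE, row.names = FALSE)
cat(sprintf("DESEQ2_VERSION\t%s\n", as.character(packageVersion("DESeq2"))))
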