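# Regenerates the lmerTest reference values frozen in test_lmm.py.
# Usage: Rscript lmer_reference.R <fixture.csv>
# The fixtures are produced by the generator calls documented alongside the
# frozen values (lumipower.synth.generate_day_metrics with the stated specs).
suppressMessages(library(lmerTest))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
d$x <- as.integer(d$condition == "winter")
fit <- lmer(m ~ 1 + x + (1 | participant_id), data = d, REML = TRUE)
s <- summary(fit)
co <- s$coefficients
vc <- as.data.frame(VarCorr(fit))
cat(sprintf(
  "alpha=%.10f beta=%.10f se=%.10f df=%.10f p=%.10e s2b=%.10f s2=%.10f\n",
  co[1, 1], co[2, 1], co[2, 2], co[2, 3], co[2, 5], vc$vcov[1], vc$vcov[2]
))
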