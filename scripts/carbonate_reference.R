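# Independent reference solver for the seawater CO2 system (base R only).
#
# Generates tests/data/carbonate_reference.csv, the frozen cross-check grid
# used by the Python carbonate tests.  Written as a separate implementation:
# constants transcribed directly from the primary literature (Lueker et al.
# 2000 K1/K2, Weiss 1974 K0, Dickson 1990 KB, DOE 1994 KW, Uppstrom 1974
# total boron), and the system solved through the DIC parameterisation of
# total alkalinity (TA is linear in DIC at fixed [H+]), rather than the
# carbonate-alkalinity subtraction used in the package.
#
# Usage: Rscript scripts/carbonate_reference.R tests/data/carbonate_reference.csv

constants <- function(temp, sal) {
  tk <- temp + 273.15
  s <- sal
  k0 <- exp(-60.2409 + 93.4517 * (100 / tk) + 23.3585 * log(tk / 100) +
            s * (0.023517 - 0.023656 * (tk / 100) + 0.0047036 * (tk / 100)^2))
  pk1 <- 3633.86 / tk - 61.2172 + 9.6777 * log(tk) - 0.011555 * s + 0.0001152 * s^2
  pk2 <- 471.78 / tk + 25.929 - 3.16967 * log(tk) - 0.01781 * s + 0.0001122 * s^2
  kb <- exp((-8966.90 - 2890.53 * sqrt(s) - 77.942 * s + 1.728 * s^1.5 - 0.0996 * s^2) / tk +
            148.0248 + 137.1942 * sqrt(s) + 1.62142 * s +
            (-24.4344 - 25.085 * sqrt(s) - 0.2474 * s) * log(tk) +
            0.053105 * sqrt(s) * tk)
  kw <- exp(148.9652 - 13847.26 / tk - 23.6521 * log(tk) +
            (118.67 / tk - 5.977 + 1.0495 * log(tk)) * sqrt(s) - 0.01615 * s)
  list(k0 = k0, k1 = 10^-pk1, k2 = 10^-pk2, kb = kb, kw = kw,
       bt = 0.000416 * s / 35)
}

# TA (mol/kg) as a function of DIC and H, plus non-carbonate terms
ta_of <- function(dic, h, k) {
  denom <- h^2 + k$k1 * h + k$k1 * k$k2
  carb_alk <- dic * (k$k1 * h + 2 * k$k1 * k$k2) / denom
  carb_alk + k$bt * k$kb / (k$kb + h) + k$kw / h - h
}

pco2_from_ta_ph <- function(ta_umol, ph, temp, sal) {
  k <- constants(temp, sal)
  h <- 10^-ph
  ta <- ta_umol * 1e-6
  nc <- k$bt * k$kb / (k$kb + h) + k$kw / h - h   # non-carbonate alkalinity
  denom <- h^2 + k$k1 * h + k$k1 * k$k2
  dic <- (ta - nc) * denom / (k$k1 * h + 2 * k$k1 * k$k2)
  co2 <- dic * h^2 / denom
  co2 / k$k0 * 1e6
}

ph_from_ta_pco2 <- function(ta_umol, pco2_uatm, temp, sal) {
  k <- constants(temp, sal)
  ta <- ta_umol * 1e-6
  co2 <- k$k0 * pco2_uatm * 1e-6
  f <- function(ph) {
    h <- 10^-ph
    hco3 <- k$k1 * co2 / h
    co3 <- k$k2 * hco3 / h
    hco3 + 2 * co3 + k$bt * k$kb / (k$kb + h) + k$kw / h - h - ta
  }
  uniroot(f, c(6, 9), tol = 1e-12)$root
}

args <- commandArgs(trailingOnly = TRUE)
out <- if (length(args) >= 1) args[[1]] else "tests/data/carbonate_reference.csv"

rows <- list()
for (ta in c(2000, 2150, 2300, 2450, 2500))
  for (ph in c(7.7, 7.9, 8.1, 8.3))
    for (temp in c(8, 13, 20))
      for (sal in c(30, 35, 38))
        rows[[length(rows) + 1]] <- data.frame(
          mode = "speciate", ta = ta, ph = ph, temp = temp, sal = sal,
          pco2 = pco2_from_ta_ph(ta, ph, temp, sal))

for (pco2 in c(400, 712, 1000))
  for (temp in c(10, 13))
    rows[[length(rows) + 1]] <- data.frame(
      mode = "solve_ph", ta = 2300, ph = ph_from_ta_pco2(2300, pco2, temp, 35),
      temp = temp, sal = 35, pco2 = pco2)

df <- do.call(rbind, rows)
df$pco2 <- sprintf("%.6f", df$pco2)
df$ph <- sprintf("%.8f", as.numeric(df$ph))
write.csv(df, out, row.names = FALSE, quote = FALSE)
cat("wrote", out, "with", nrow(df), "rows\n")
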