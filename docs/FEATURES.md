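# The 53-feature dictionary

Features are computed per session on the **target segment**, in the frozen
canonical order below (the order of the feature-matrix CSV columns). The
first 22 come from the original BPM signal `X_1..X_N`; the remaining 31 from
the baseline-normalized signal `X~_i = X_i - mean(neutral segment)`.

Conventions: *runs* are maximal monotone stretches (up / down / flat) of the
signal; consecutive runs share their boundary sample. "std" is the
population standard deviation. Statistics of an empty run collection are 0.
Mean-of-difference features average **absolute** differences by default
(`diff_absolute`). Down-run amplitudes and slopes are reported as positive
magnitudes.

## Original-signal features (22)

| # | Name | Definition |
|---|------|------------|
| 1 | `rate_diff1_mean` | mean of abs first differences, `1/(N-1) * sum(abs(X_{n+1} - X_n))` |
| 2 | `rate_diff2_mean` | mean of abs two-step differences, `1/(N-2) * sum(abs(X_{n+2} - X_n))` |
| 3 | `rate_range` | `max(X) - min(X)` |
| 4 | `rate_data_entropy` | Shannon entropy (bits) of the empirical distribution of distinct integer-rounded BPM values |
| 5 | `max_ratio` | `max(X) / N` |
| 6 | `min_ratio` | `min(X) / N` |
| 7 | `rate_adjacent_data_root_mean` | RMS of adjacent differences, `sqrt(mean((X_{n+1} - X_n)^2))` |
| 8–12 | `rate_down_time_{max,min,median,mean,std}` | statistics of down-run durations (s) |
| 13–17 | `rate_up_time_{max,min,median,mean,std}` | statistics of up-run durations (s) |
| 18–22 | `rate_time_continue_{max,min,median,mean,std}` | statistics of flat-run (plateau) durations (s) |

## Normalized-signal features (31)

| # | Name | Definition |
|---|------|------------|
| 23–27 | `rate_down_slope_{max,min,median,mean,std}` | statistics of per-down-run `abs(amplitude) / duration` |
| 28–31 | `rate_up_amplitude_{max,median,mean,std}` | statistics of per-up-run amplitude (no `min` member; four statistics only) |
| 32–36 | `rate_down_amplitude_{max,min,median,mean,std}` | statistics of per-down-run `abs(amplitude)` |
| 37–41 | `25_mean_{max,min,median,mean,std}` | statistics of the 25-sample moving average of `X~` ("valid" mode, output length N-24) |
| 42 | `rate_data_mean` | `mean(X~)` — the average deviation from the neutral baseline |
| 43 | `rate_data_var` | unbiased sample variance of `X~` (divisor N-1) |
| 44–48 | `rate_data_normalized_diff1_{max,min,std,median,mean}` | statistics of the first-difference series of `X~`; the `mean` member follows `diff_absolute` |
| 49–53 | `rate_data_normalized_diff2_{max,min,std,median,mean}` | statistics of the two-step-difference series of `X~`; the `mean` member follows `diff_absolute` |

The canonical order is fingerprinted in the test suite (SHA-256 of the
joined name list); any reordering or rename fails loudly.
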