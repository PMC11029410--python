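currency:
  report_ngn: false
  usd_to_ngn: 358.0
industry:
  annual_frac: 0.01
  cost_per_product_usd: 42500.0
  products: 331
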