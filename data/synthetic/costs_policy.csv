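component,kind,amount_usd,sd_usd
legislation,oneoff,100000.0,20000.0
nafdac_monitoring_enforcement,annual,150000.0,30000.0
son_standards,annual,40000.0,8000.0
cpc_campaigns,annual,50000.0,10000.0
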