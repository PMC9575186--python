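1dc960a83a02ef86359fb0f84e5d320ac5c0143f4114659e2e64a3da7e242d6d  moffitt_tumor_synthetic.tsv
908a57568769eb7ee941fc2c6b7dcf332157ee8d3f455a2a2b4f6216bef3ec14  moffitt_stroma_synthetic.tsv
0c53cab04ea67d75dccc521e7ba064453a1315b2982f7748d51bf36bb7a0c571  collisson_synthetic.tsv
55c0866a036febc9d79484cd41d9207dc5f680bd828f792453f158a4ca61c189  bailey_synthetic.tsv
48dc69692f412019ac45f03a950ef3383284d42352a2f02678d5694df2743435  puleo_synthetic.tsv
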