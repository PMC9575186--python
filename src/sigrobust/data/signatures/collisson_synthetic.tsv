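gene	class
COLL001	classical
COLL002	quasi-mesenchymal
COLL003	exocrine-like
COLL004	classical
COLL005	quasi-mesenchymal
COLL006	exocrine-like
COLL007	classical
COLL008	quasi-mesenchymal
COLL009	exocrine-like
COLL010	classical
COLL011	quasi-mesenchymal
COLL012	exocrine-like
COLL013	classical
COLL014	quasi-mesenchymal
COLL015	exocrine-like
COLL016	classical
COLL017	quasi-mesenchymal
COLL018	exocrine-like
COLL019	classical
COLL020	quasi-mesenchymal
COLL021	exocrine-like
COLL022	classical
COLL023	quasi-mesenchymal
COLL024	exocrine-like
COLL025	classical
COLL026	quasi-mesenchymal
COLL027	exocrine-like
COLL028	classical
COLL029	quasi-mesenchymal
COLL030	exocrine-like
COLL031	classical
COLL032	quasi-mesenchymal
COLL033	exocrine-like
COLL034	classical
COLL035	quasi-mesenchymal
COLL036	exocrine-like
COLL037	classical
COLL038	quasi-mesenchymal
COLL039	exocrine-like
COLL040	classical
COLL041	quasi-mesenchymal
COLL042	exocrine-like
COLL043	classical
COLL044	quasi-mesenchymal
COLL045	exocrine-like
COLL046	classical
COLL047	quasi-mesenchymal
COLL048	exocrine-like
COLL049	classical
COLL050	quasi-mesenchymal
COLL051	exocrine-like
COLL052	classical
COLL053	quasi-mesenchymal
COLL054	exocrine-like
COLL055	classical
COLL056	quasi-mesenchymal
COLL057	exocrine-like
COLL058	classical
COLL059	quasi-mesenchymal
COLL060	exocrine-like
COLL061	classical
COLL062	quasi-mesenchymal
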