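concept_id_1,concept_id_2,relationship_id
45700001,45500001,CIP to ATC
45700002,45500002,CIP to ATC
45700003,45500003,CIP to ATC
45700004,45500004,CIP to ATC
45700005,45500005,CIP to ATC
45700006,45500006,CIP to ATC
45700007,45500007,CIP to ATC
45700008,45500008,CIP to ATC
45700009,45500009,CIP to ATC
45700010,45500001,CIP to ATC
45700011,45500002,CIP to ATC
45700012,45500003,CIP to ATC
45700013,45500004,CIP to ATC
45700014,45500005,CIP to ATC
45700015,45500006,CIP to ATC
45700016,45500007,CIP to ATC
45700017,45500008,CIP to ATC
45700018,45500009,CIP to ATC
45700019,45500001,CIP to ATC
45700020,45500002,CIP to ATC
45500001,45600001,ATC to RxNorm
45500002,45600002,ATC to RxNorm
45500003,45600003,ATC to RxNorm
45500004,45600004,ATC to RxNorm
45500005,45600005,ATC to RxNorm
45500006,45600006,ATC to RxNorm
45500007,45600007,ATC to RxNorm
45500008,45600008,ATC to RxNorm
45500009,45600010,ATC to RxNorm
45500010,45600011,ATC to RxNorm
45500011,45600012,ATC to RxNorm
45500012,45600013,ATC to RxNorm
45600010,45600004,RxNorm has ingredient
45600010,45600009,RxNorm has ingredient
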