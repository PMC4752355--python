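atc_code,substance,ddd_amount_mg,version
N05BA12,alprazolam,1.0,ATC-DDD-2014
N05BA05,clorazepate,20.0,ATC-DDD-2014
N03AE01,clonazepam,8.0,ATC-DDD-2014
N05BA01,diazepam,10.0,ATC-DDD-2014
N05BA06,lorazepam,2.5,ATC-DDD-2014
N06AB04,citalopram,20.0,ATC-DDD-2014
N06AB10,escitalopram,10.0,ATC-DDD-2014
N06AB03,fluoxetine,20.0,ATC-DDD-2014
N06AB05,paroxetine,20.0,ATC-DDD-2014
N06AB06,sertraline,50.0,ATC-DDD-2014
N06AX16,venlafaxine,100.0,ATC-DDD-2014
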