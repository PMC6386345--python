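canonical,drug_class,variants,match_as_word
cisplatin,platinum,platinol|cddp|cis-platin|cisplatnum|cisplantin,true
carboplatin,platinum,paraplatin|carbo|cbdca|carboplaten|carboplatnin,true
pemetrexed,pemetrexed,alimta|pemetrexate|pemetrexed disodium|premetrexed,true
bevacizumab,bevacizumab,avastin|bev|bevacuzimab|bevacizamab,true
erlotinib,tki,tarceva|erlotnib|erlotinab,true
gefitinib,tki,iressa|gefitnib,true
afatinib,tki,gilotrif|afatnib,true
crizotinib,tki,xalkori|crizotnib,true
paclitaxel,other_chemo,taxol|paclitaxol|pacletaxel,true
nab-paclitaxel,other_chemo,abraxane|nab paclitaxel|nabpaclitaxel,true
docetaxel,other_chemo,taxotere|docetaxol,true
gemcitabine,other_chemo,gemzar|gem|gemcitabene|gemcytabine,true
vinorelbine,other_chemo,navelbine|vinorelbin,true
etoposide,other_chemo,vp-16|vepesid|etopocide,true
irinotecan,other_chemo,camptosar|cpt-11,true

kind,pattern,scope,direction
negation,not a candidate for,mention_window,forward
negation,not eligible for,mention_window,forward
negation,no plans? for,mention_window,forward
negation,did not receive,mention_window,forward
negation,expired (before|prior to) receiving,mention_window,forward
negation,died (before|prior to) receiving,mention_window,forward
negation,refused,mention_window,both
negation,declined,mention_window,both
negation,never (received|given|started),mention_window,both
negation,not (given|administered|started|recommended),mention_window,both
negation,deferred,mention_window,both
uncertainty,unknown (if|whether) (given|received|administered|started),mention_window,both
uncertainty,unclear (if|whether) (given|received),mention_window,both
uncertainty,to be determined,mention_window,both
uncertainty,pending,mention_window,both
no_treatment,(patient|pt) refused( all| any)?( systemic)? (treatment|therapy|chemo(therapy)?),whole_record,forward
no_treatment,refused( all| any)?( systemic)? (treatment|therapy|chemo(therapy)?),whole_record,forward
no_treatment,declined( all| any)?( systemic)? (treatment|therapy|chemo(therapy)?),whole_record,forward
no_treatment,opted for hospice( care)?( instead of (treatment|therapy|chemo(therapy)?))?,whole_record,forward
no_treatment,hospice (instead of|in lieu of) (treatment|therapy|chemo(therapy)?),whole_record,forward
no_treatment,no (systemic )?(treatment|therapy|chemo(therapy)?)( was)? (given|administered|planned|recommended),whole_record,forward
no_treatment,(died|expired) (before|prior to)( receiving)?( any)? (treatment|therapy|chemo(therapy)?),whole_record,forward
no_treatment,comfort (care|measures) only,whole_record,forward
no_treatment,best supportive care only,whole_record,forward
no_treatment,(treatment|therapy|chemo(therapy)?) not (given|administered|planned),whole_record,forward
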