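{
 "demand": {
  "base_population": 220000.0,
  "referral_rate": 8.586061293276552,
  "dvt_positive_fraction": 0.3,
  "annual_growth": 0.01,
  "horizon_years": 5,
  "prevalence_per_100k": 104.6
 },
 "mix": {
  "group_fractions": {
   "provoked": 0.4,
   "unprovoked": 0.35,
   "recurrent": 0.25
  },
  "duration_mix": {
   "provoked": {
    "3": 0.20000000000000007,
    "6": 0.29999999999999993,
    "12": 0.49999999999999994
   },
   "unprovoked": {
    "3": 0.02000000000000003,
    "6": 0.13000000000000003,
    "12": 0.8499999999999999
   },
   "recurrent": {
    "3": 1.1102230246251566e-17,
    "6": 0.05000000000000004,
    "12": 0.95
   }
  }
 },
 "regimens": {
  "standard": {
   "name": "standard",
   "visits_by_duration": {
    "3": 9,
    "6": 14,
    "12": 24
   },
   "drug_phases": [
    {
     "drug": "LMWH",
     "length_days": 8
    },
    {
     "drug": "warfarin",
     "length_days": "remainder"
    }
   ]
  },
  "NOAC": {
   "name": "NOAC",
   "visits_by_duration": {
    "3": 2,
    "6": 2,
    "12": 2
   },
   "drug_phases": [
    {
     "drug": "NOAC",
     "length_days": "remainder"
    }
   ]
  }
 },
 "resources": {
  "headcount": {
   "nurse": 8.0,
   "doctor": 4.0,
   "radiologist": 2.0,
   "bed": 6.0,
   "cs_nurse": 6.0
  },
  "dvt_allocation": {
   "nurse": 0.5,
   "doctor": 0.5,
   "radiologist": 0.5,
   "bed": 0.5,
   "cs_nurse": 0.5
  },
  "service_minutes": {
   "history": 1.0000000000000002,
   "wells_score": 0.5000000000000001,
   "d_dimer": 0.5000000000000001,
   "consultant_exam": 5.925793357935846,
   "ultrasound": 12.0,
   "hospital_visit_nurse": 9.09417886273405,
   "hospital_visit_doctor": 3.2489586874344774,
   "community_visit_nurse": 6.772027263007257,
   "bed_occupancy_first_visit": 60.0
  }
 },
 "costs": {
  "first_visit": {
   "hospital": 60.00000000000001,
   "community": 120.0
  },
  "followup_visit": {
   "hospital": 41.234409025071606,
   "community": 2.0000000000000004
  },
  "drug_cost_per_day": {
   "LMWH": 7.12,
   "warfarin": 0.06,
   "NOAC": 0.8453547414564423
  },
  "staff_hourly_rate": {
   "nurse": 99.99999999999999,
   "doctor": 175.7287499855775,
   "radiologist": 40.00000000000001,
   "cs_nurse": 99.99999999999999
  }
 },
 "star": {
  "interventions": {
   "NOAC_community": {
    "benefit": 130.63483532812862,
    "feasibility": 0.85
   },
   "standard_community": {
    "benefit": 60.66146595973778,
    "feasibility": 0.8
   },
   "NOAC_hospital": {
    "benefit": 53.47190276853367,
    "feasibility": 0.8
   },
   "standard_hospital": {
    "benefit": 49.07414556897808,
    "feasibility": 0.75
   }
  },
  "vfm_scale": 1000.0
 },
 "pathway": {
  "referral_source_mix": {
   "GP": 0.55,
   "A&E": 0.2,
   "outpatient": 0.15,
   "community": 0.1
  },
  "hospital_retention": 0.3119796357945114
 },
 "provenance": {
  "demand.base_population": "printed",
  "demand.referral_rate": "calibrated",
  "demand.dvt_positive_fraction": "assumed",
  "demand.annual_growth": "printed",
  "demand.horizon_years": "printed",
  "demand.prevalence_per_100k": "printed",
  "mix.group_fractions": "assumed",
  "mix.duration_mix": "calibrated",
  "regimens.standard.visits_by_duration": "printed",
  "regimens.standard.drug_phases": "printed",
  "regimens.NOAC.visits_by_duration": "printed",
  "regimens.NOAC.drug_phases": "printed",
  "resources.headcount": "assumed",
  "resources.dvt_allocation": "assumed",
  "resources.service_minutes.history": "calibrated",
  "resources.service_minutes.wells_score": "calibrated",
  "resources.service_minutes.d_dimer": "calibrated",
  "resources.service_minutes.consultant_exam": "calibrated",
  "resources.service_minutes.ultrasound": "assumed",
  "resources.service_minutes.hospital_visit_nurse": "calibrated",
  "resources.service_minutes.hospital_visit_doctor": "calibrated",
  "resources.service_minutes.community_visit_nurse": "calibrated",
  "resources.service_minutes.bed_occupancy_first_visit": "assumed",
  "costs.first_visit.hospital": "calibrated",
  "costs.first_visit.community": "assumed",
  "costs.followup_visit.hospital": "calibrated",
  "costs.followup_visit.community": "calibrated",
  "costs.drug_cost_per_day.LMWH": "assumed",
  "costs.drug_cost_per_day.warfarin": "assumed",
  "costs.drug_cost_per_day.NOAC": "calibrated",
  "costs.staff_hourly_rate": "calibrated",
  "star.interventions.benefit": "calibrated",
  "star.interventions.feasibility": "assumed",
  "star.vfm_scale": "assumed",
  "pathway.referral_source_mix": "assumed",
  "pathway.hospital_retention": "calibrated"
 }
}
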